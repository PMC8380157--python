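import numpy as np
import pytest

import fdgnet as fg
from fdgnet import nn
from fdgnet.hybrid import _digest, _svm_bytes, infer_task_labels
from fdgnet.svm import softmax_head, svm_score
from conftest import tiny_backbone_config, grouped_split


@pytest.fixture(scope="module")
def small_hybrid(tiny_cohort):
    """A quickly-trained AD-vs-NC hybrid on the 32^3 cohort."""
    pair = tiny_cohort.restrict_labels(["AD", "NC"])
    train, verif, _test = grouped_split(pair, n_test=1, n_verif=1, seed=3)
    model, trace = fg.alternate_train(
        train, verif, tiny_backbone_config(), fg.SVMTrainingConfig(seed=0),
        fg.AlternationConfig(rounds=1, finetune_epochs=1, seed=5),
        pretrain_opts=fg.TrainOptions(epochs=2, lr=3e-2, momentum=0.9),
        finetune_opts=fg.TrainOptions(lr=3e-3, momentum=0.9))
    return model, trace, train, verif


class TestAttachHead:
    def test_composition_identity(self, small_hybrid, rng):
        model, *_ = small_hybrid
        v = fg.Volume(rng.normal(size=(32, 32, 32)))
        emb = fg.extract_embedding(model.backbone, v)
        expected = softmax_head(svm_score(model.svm, emb)).y0
        got = model.predict_proba([_as_sample(v)])[0]
        assert got == pytest.approx(expected, abs=1e-6)

    def test_sign_mode_reproduces_sign_predict(self, small_hybrid, tiny_cohort):
        model, *_ = small_hybrid
        pair = tiny_cohort.restrict_labels(["AD", "NC"])
        model_sign = fg.HybridModel(backbone=model.backbone, svm=model.svm,
                                    pos_label="AD", neg_label="NC", head_mode="sign")
        emb = fg.extract_embeddings(model.backbone, pair)
        expected = [("AD" if p == 1 else "NC")
                    for p in fg.svm_sign_predict(model.svm, emb)]
        assert model_sign.predict_labels(pair) == expected

    def test_dimension_mismatch_rejected(self, small_hybrid):
        model, *_ = small_hybrid
        bad_svm = fg.SVMModel(support_vectors=np.zeros((2, 99)), alphas=np.ones(2),
                              labels=np.array([1.0, -1.0]), bias=0.0, q=2)
        with pytest.raises(ValueError, match="dimension"):
            fg.attach_svm_head(model.backbone, bad_svm)

    def test_gradient_reaches_backbone_not_svm(self, small_hybrid, rng):
        """y0 responds to a backbone parameter perturbation, and the fine-tune
        optimizer's parameter set excludes every SVM quantity."""
        model, *_ = small_hybrid
        v = fg.Volume(rng.normal(size=(32, 32, 32)))

        def y0():
            return model.predict_proba([_as_sample(v)])[0]

        conv = next(l for l in model.backbone.feature_layers if l.params)
        base = y0()
        old = conv.params["w"].copy()
        conv.params["w"] += 1e-3
        perturbed = y0()
        conv.params["w"][...] = old
        assert perturbed != base  # finite-difference probe: gradient path exists

        opt_layers = model.backbone.feature_parameter_layers()
        opt_params = {id(p) for l in opt_layers for p in l.params.values()}
        for arr in (model.svm.support_vectors, model.svm.alphas, model.svm.labels):
            assert id(arr) not in opt_params


class TestFinetune:
    def test_svm_bit_unchanged(self, small_hybrid):
        model, _, train, verif = small_hybrid
        before = _svm_bytes(model.svm)
        fg.finetune_backbone(model, train,
                             fg.AlternationConfig(rounds=1, finetune_epochs=1),
                             fg.TrainOptions(lr=1e-3), seed=0)
        assert _svm_bytes(model.svm) == before

    def test_zero_epochs_is_identity(self, small_hybrid):
        model, *_ = small_hybrid
        before = model.backbone.parameter_bytes()
        fg.finetune_backbone(model, _dummy_data(model),
                             fg.AlternationConfig(rounds=1, finetune_epochs=0),
                             fg.TrainOptions(), seed=0)
        assert model.backbone.parameter_bytes() == before

    def test_empty_dataset_rejected(self, small_hybrid):
        model, *_ = small_hybrid
        with pytest.raises(ValueError, match="empty"):
            fg.finetune_backbone(model, fg.Dataset([]),
                                 fg.AlternationConfig(rounds=1, finetune_epochs=1))

    def test_loss_not_increased_on_separable_data(self, small_hybrid):
        model, _, train, _ = small_hybrid
        before = model.mean_loss(train)
        fg.finetune_backbone(model, train,
                             fg.AlternationConfig(rounds=1, finetune_epochs=1),
                             fg.TrainOptions(lr=1e-3, momentum=0.9), seed=1)
        assert model.mean_loss(train) <= before + 0.05


class TestRefit:
    def test_backbone_unchanged_and_deterministic(self, small_hybrid):
        model, _, train, _ = small_hybrid
        bb_before = _digest(model.backbone.parameter_bytes())
        fg.refit_svm(model, train, fg.SVMTrainingConfig(seed=7))
        first = model.svm.alphas.copy()
        assert _digest(model.backbone.parameter_bytes()) == bb_before
        fg.refit_svm(model, train, fg.SVMTrainingConfig(seed=7))
        np.testing.assert_array_equal(model.svm.alphas, first)

    def test_constraints_on_new_embeddings(self, small_hybrid):
        model, _, train, _ = small_hybrid
        fg.refit_svm(model, train, fg.SVMTrainingConfig(seed=7))
        assert abs((model.svm.alphas * model.svm.labels).sum()) < 1e-6
        assert np.all(model.svm.alphas >= 0)
        assert np.all(model.svm.alphas <= model.svm.C + 1e-9)


class TestAlternate:
    def test_trace_bookkeeping_two_rounds(self, small_hybrid):
        _, trace, *_ = small_hybrid
        assert list(trace["phase"][:2]) == ["pretrain", "initial_svm"]
        assert set(trace["phase"][2:]) == {"finetune", "refit_svm"}
        assert np.isfinite(trace["loss"].astype(float)).all()

    def test_phase_exclusivity_checksums(self, small_hybrid):
        _, trace, *_ = small_hybrid
        for row in trace.iloc[2:].itertuples():
            bb_moved = row.backbone_before != row.backbone_after
            svm_moved = row.svm_before != row.svm_after
            assert not (bb_moved and svm_moved)
            if row.phase == "finetune":
                assert row.svm_before == row.svm_after
            if row.phase == "refit_svm":
                assert row.backbone_before == row.backbone_after

    def test_subject_overlap_rejected(self, tiny_cohort):
        pair = tiny_cohort.restrict_labels(["AD", "NC"])
        with pytest.raises(ValueError, match="leakage"):
            fg.alternate_train(pair, pair, tiny_backbone_config(),
                               fg.SVMTrainingConfig(),
                               fg.AlternationConfig(rounds=1, finetune_epochs=0))

    def test_infinite_tolerance_stops_after_one_round(self, tiny_cohort):
        pair = tiny_cohort.restrict_labels(["MCI", "NC"])
        train, verif, _ = grouped_split(pair, 1, 1, seed=0)
        _, trace = fg.alternate_train(
            train, verif, tiny_backbone_config(), fg.SVMTrainingConfig(seed=0),
            fg.AlternationConfig(rounds=5, finetune_epochs=1, seed=1,
                                 convergence_tol=np.inf),
            pretrain_opts=fg.TrainOptions(epochs=1, lr=1e-2))
        assert trace["round"].max() == 1

    def test_deterministic_given_seed(self, tiny_cohort):
        pair = tiny_cohort.restrict_labels(["AD", "MCI"])
        train, verif, _ = grouped_split(pair, 1, 1, seed=0)
        traces = []
        for _ in range(2):
            model, trace = fg.alternate_train(
                train, verif, tiny_backbone_config(), fg.SVMTrainingConfig(seed=2),
                fg.AlternationConfig(rounds=1, finetune_epochs=1, seed=2),
                pretrain_opts=fg.TrainOptions(epochs=1, lr=1e-2))
            traces.append(trace)
        assert traces[0].equals(traces[1])

    def test_severity_ordering_picks_positive_label(self, tiny_cohort):
        assert infer_task_labels(tiny_cohort.restrict_labels(["AD", "NC"])) == ("AD", "NC")
        assert infer_task_labels(tiny_cohort.restrict_labels(["MCI", "NC"])) == ("MCI", "NC")
        assert infer_task_labels(tiny_cohort.restrict_labels(["AD", "MCI"])) == ("AD", "MCI")


class TestMarginProperty:
    def test_mean_margin_not_decreased_by_finetune(self, tiny_cohort):
        """Fine-tuning through the frozen head should push training samples
        away from the hyperplane on separable phantoms (checked on 3 seeds,
        1 failure allowed)."""
        pair = tiny_cohort.restrict_labels(["AD", "NC"])
        train, verif, _ = grouped_split(pair, 1, 1, seed=2)
        ok = 0
        for seed in range(3):
            model, _ = fg.alternate_train(
                train, verif, tiny_backbone_config(), fg.SVMTrainingConfig(seed=seed),
                fg.AlternationConfig(rounds=1, finetune_epochs=0, seed=seed),
                pretrain_opts=fg.TrainOptions(epochs=2, lr=3e-2, momentum=0.9))
            y = np.where(model.targets(train) == 1, 1.0, -1.0)
            before = float(np.mean(y * model.scores(train)))
            fg.finetune_backbone(model, train,
                                 fg.AlternationConfig(rounds=1, finetune_epochs=1),
                                 fg.TrainOptions(lr=3e-3, momentum=0.9), seed=seed)
            after = float(np.mean(y * model.scores(train)))
            ok += after >= before - 1e-6
        assert ok >= 2


class TestBundle:
    def test_roundtrip(self, small_hybrid, tmp_path, tiny_cohort):
        model, trace, *_ = small_hybrid
        fg.save_bundle(model, trace, tmp_path / "b")
        back = fg.load_bundle(tmp_path / "b")
        pair = tiny_cohort.restrict_labels(["AD", "NC"])
        np.testing.assert_allclose(back.scores(pair), model.scores(pair), atol=1e-6)
        assert (back.pos_label, back.neg_label) == ("AD", "NC")


def _as_sample(v):
    return fg.Sample(v, "probe", "0", "NC")


def _dummy_data(model):
    rng = np.random.default_rng(0)
    vols = [fg.Sample(fg.Volume(rng.normal(size=(32, 32, 32))), f"d{i}", "0",
                      lab) for i, lab in enumerate(["AD", "NC"])]
    return fg.Dataset(vols)
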