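import warnings

import numpy as np
import pytest
import fdgnet as fg
from fdgnet import svm as S
from oracles import full_alphas, qp_dual_optimum


class TestPolyKernel:
    def test_orthogonal_vectors(self):
        assert S.poly_kernel(np.array([1.0, 0.0]), np.array([0.0, 2.0]), 5) == 1.0

    def test_unit_dot_squared(self):
        assert S.poly_kernel(np.array([1.0]), np.array([1.0]), 2) == 4.0

    def test_matches_multinomial_expansion(self, rng):
        # (x.z + 1)^3 expanded term-by-term via the multinomial theorem
        x, z = rng.normal(size=5), rng.normal(size=5)
        import math
        dot = float(x @ z)
        brute = sum(math.comb(3, k) * dot ** k for k in range(4))
        np.testing.assert_allclose(S.poly_kernel(x, z, 3), brute, rtol=1e-12)

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            S.poly_kernel(np.ones(3), np.ones(4), 1)


class TestTrainSMO:
    def test_two_point_analytic(self):
        # dual: max 2a - a^2 K with a1=a2=a, K=(1+1)=2 (q=1) -> a=1/2... solved
        # analytically the boundary is x=0, scores +-0.5 at x=+-0.5
        m = S.train_smo(np.array([[1.0], [-1.0]]), np.array([1.0, -1.0]),
                        S.SVMTrainingConfig(C=10.0, q=1))
        assert m.n_support == 2
        assert abs(S.svm_score(m, np.array([0.0]))) < 1e-9
        assert S.svm_score(m, np.array([0.5])) == pytest.approx(0.5, abs=1e-6)
        assert S.svm_sign_predict(m, np.array([0.5])) == 1
        assert S.svm_sign_predict(m, np.array([-0.5])) == -1

    def test_xor_separable_with_quadratic_kernel(self):
        X = np.array([[0, 0], [1, 1], [0, 1], [1, 0]], dtype=float)
        y = np.array([1.0, 1.0, -1.0, -1.0])
        m = S.train_smo(X, y, S.SVMTrainingConfig(C=10.0, q=2))
        np.testing.assert_array_equal(S.svm_sign_predict(m, X), y)

    def test_constraints_hold_at_convergence(self, rng):
        X = rng.normal(size=(20, 3))
        y = np.where(X[:, 0] + 0.3 * rng.normal(size=20) > 0, 1.0, -1.0)
        if len(set(y)) < 2:
            y[0] = -y[0]
        cfg = S.SVMTrainingConfig(C=2.0, q=2, tol=1e-3)
        m = S.train_smo(X, y, cfg)
        a = full_alphas(m, X)
        assert abs((a * y).sum()) < 1e-6
        assert np.all(a >= -1e-9) and np.all(a <= cfg.C + 1e-9)

    def test_kkt_margin_on_non_bound_support_vectors(self):
        rng = np.random.default_rng(3)
        X = np.vstack([rng.normal(2, 1, size=(10, 2)), rng.normal(-2, 1, size=(10, 2))])
        y = np.r_[np.ones(10), -np.ones(10)]
        cfg = S.SVMTrainingConfig(C=5.0, q=1, tol=1e-4, max_passes=500)
        m = S.train_smo(X, y, cfg)
        nb = (m.alphas > 1e-6) & (m.alphas < cfg.C - 1e-6)
        s = S.svm_score(m, m.support_vectors[nb])
        np.testing.assert_allclose(m.labels[nb] * s, 1.0, atol=5e-3)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            S.train_smo(np.zeros((3, 2)), np.ones(3), S.SVMTrainingConfig())

    def test_matches_reference_svm_predictions(self, rng):
        sklearn = pytest.importorskip("sklearn.svm")
        X = rng.normal(size=(30, 2))
        y = np.where(X[:, 0] ** 2 + X[:, 1] > 0.5, 1.0, -1.0)
        if len(set(y)) < 2:
            y[0] = -y[0]
        m = S.train_smo(X, y, S.SVMTrainingConfig(C=1.0, q=2, tol=1e-4, max_passes=500))
        ref = sklearn.SVC(kernel="poly", degree=2, gamma=1.0, coef0=1.0, C=1.0).fit(X, y)
        grid = rng.normal(size=(50, 2))
        agree = np.mean(S.svm_sign_predict(m, grid) == ref.predict(grid))
        assert agree >= 0.95

    def test_dual_objective_matches_qp_oracle_small(self, rng):
        X = rng.normal(size=(8, 2))
        y = np.where(rng.random(8) < 0.5, 1.0, -1.0)
        y[:2] = [1.0, -1.0]
        cfg = S.SVMTrainingConfig(C=1.0, q=2, tol=1e-4, max_passes=500)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            m = S.train_smo(X, y, cfg)
        K = (X @ X.T + 1.0) ** cfg.q
        obj = S.dual_objective(full_alphas(m, X), y, K)
        ref = qp_dual_optimum(X, y, cfg.C, cfg.q)
        assert abs(obj - ref) <= 1e-4 * max(1.0, abs(ref))


class TestScoreAndSign:
    def test_empty_expansion_returns_bias(self):
        m = S.SVMModel(support_vectors=np.zeros((0, 4)), alphas=np.zeros(0),
                       labels=np.zeros(0), bias=0.7, q=2)
        assert S.svm_score(m, np.ones(4)) == 0.7

    def test_sign_tie_break_and_signs(self):
        m = S.SVMModel(support_vectors=np.zeros((0, 1)), alphas=np.zeros(0),
                       labels=np.zeros(0), bias=0.0, q=1)
        assert S.svm_sign_predict(m, np.ones(1)) == 1  # s = 0 -> +1
        m.bias = 0.3
        assert S.svm_sign_predict(m, np.ones(1)) == 1
        m.bias = -2.0
        assert S.svm_sign_predict(m, np.ones(1)) == -1

    def test_dimension_mismatch(self):
        m = S.SVMModel(support_vectors=np.zeros((2, 3)), alphas=np.ones(2),
                       labels=np.array([1.0, -1.0]), bias=0.0, q=1)
        with pytest.raises(ValueError):
            S.svm_score(m, np.ones(4))

    def test_score_gradient_matches_fd(self, rng):
        m = S.SVMModel(support_vectors=rng.normal(size=(5, 3)),
                       alphas=rng.uniform(0.1, 1, 5),
                       labels=np.array([1, -1, 1, 1, -1.0]), bias=0.2, q=3)
        x = rng.normal(size=3)
        g = S.score_gradient(m, x)
        eps = 1e-6
        for i in range(3):
            e = np.zeros(3)
            e[i] = eps
            fd = (S.svm_score(m, x + e) - S.svm_score(m, x - e)) / (2 * eps)
            assert abs(fd - g[i]) < 1e-5 * max(1.0, abs(fd))


class TestSoftmaxHead:
    def test_symmetry_at_zero(self):
        out = S.softmax_head(0.0)
        assert out.y0 == out.y1 == 0.5

    def test_saturation_limits(self):
        assert S.softmax_head(1e4).y0 == pytest.approx(1.0, abs=1e-9)
        assert S.softmax_head(-1e4).y0 == pytest.approx(0.0, abs=1e-9)
        assert np.isfinite(S.softmax_head(9999.0).s)

    @pytest.mark.parametrize("s", [-3.0, -0.7, 0.2, 5.0])
    def test_equals_logistic_closed_form(self, s):
        assert S.softmax_head(s).y0 == pytest.approx(1.0 / (1.0 + np.exp(-2 * s)),
                                                     abs=1e-12)

    def test_probabilities_sum_to_one(self, rng):
        for s in rng.normal(scale=3, size=20):
            out = S.softmax_head(float(s))
            assert out.y0 + out.y1 == pytest.approx(1.0, abs=1e-12)


class TestCrossEntropy:
    def test_perfect_confidence_limit(self):
        assert S.binary_cross_entropy([1], [1 - 1e-9]) == pytest.approx(0.0, abs=1e-8)

    def test_uninformative_is_log2(self):
        assert S.binary_cross_entropy([1], [0.5]) == pytest.approx(np.log(2))

    def test_matches_per_term_summation(self, rng):
        p = np.array([1.0, 0.0, 1.0])
        y0 = rng.uniform(0.05, 0.95, 3)
        by_hand = -sum(pi * np.log(yi) + (1 - pi) * np.log(1 - yi)
                       for pi, yi in zip(p, y0))
        assert S.binary_cross_entropy(p, y0) == pytest.approx(by_hand, rel=1e-12)

    def test_degenerate_probability_clipped_with_warning(self):
        with pytest.warns(UserWarning, match="clipped"):
            h = S.binary_cross_entropy([1.0], [1.0])
        assert np.isfinite(h)

    def test_loss_monotone_in_margin(self):
        s = np.linspace(-5, 5, 41)
        h_pos = [S.binary_cross_entropy([1], [S.softmax_head(v).y0]) for v in s]
        h_neg = [S.binary_cross_entropy([0], [S.softmax_head(v).y0]) for v in s]
        assert np.all(np.diff(h_pos) < 0)  # strictly decreasing in s
        assert np.all(np.diff(h_neg) > 0)  # strictly increasing in s

    def test_analytic_gradient_matches_finite_differences(self):
        for s in (-2.0, -0.3, 0.0, 0.8, 3.0):
            for p in (0.0, 1.0):
                _, g = S.head_loss_and_grad(np.array([s]), np.array([p]))
                eps = 1e-7
                hp = S.binary_cross_entropy([p], [S.softmax_head(s + eps).y0])
                hm = S.binary_cross_entropy([p], [S.softmax_head(s - eps).y0])
                assert abs((hp - hm) / (2 * eps) - g[0]) < 1e-6


class TestSerialization:
    def test_roundtrip(self, tmp_path, rng):
        X = rng.normal(size=(10, 2))
        y = np.r_[np.ones(5), -np.ones(5)]
        m = S.train_smo(X, y, S.SVMTrainingConfig(C=1.0, q=2))
        S.save_svm(m, tmp_path / "m.npz")
        back = S.load_svm(tmp_path / "m.npz")
        probe = rng.normal(size=(7, 2))
        np.testing.assert_allclose(S.svm_score(back, probe), S.svm_score(m, probe))

    def test_csv_export(self, tmp_path):
        m = S.SVMModel(support_vectors=np.eye(2), alphas=np.array([0.5, 0.5]),
                       labels=np.array([1.0, -1.0]), bias=0.0, q=1)
        S.export_svm_csv(m, tmp_path / "sv.csv")
        import pandas as pd
        df = pd.read_csv(tmp_path / "sv.csv")
        assert list(df.columns) == ["index", "alpha", "y", "weight"]
        np.testing.assert_allclose(df["weight"], [0.5, -0.5])


class TestFeatureStandardization:
    def test_equals_training_on_prestandardized_features(self, rng):
        X = rng.normal(3.0, 5.0, size=(20, 3))
        y = np.where(X[:, 0] > 3.0, 1.0, -1.0)
        y[:2] = [1.0, -1.0]
        m_std = S.train_smo(X, y, S.SVMTrainingConfig(C=2.0, q=2, seed=0,
                                                      standardize=True))
        Xz = (X - X.mean(axis=0)) / X.std(axis=0)
        m_ref = S.train_smo(Xz, y, S.SVMTrainingConfig(C=2.0, q=2, seed=0))
        probe = rng.normal(3.0, 5.0, size=(10, 3))
        probe_z = (probe - X.mean(axis=0)) / X.std(axis=0)
        np.testing.assert_allclose(S.svm_score(m_std, probe),
                                   S.svm_score(m_ref, probe_z), atol=1e-8)

    def test_gradient_includes_scale_chain(self, rng):
        X = rng.normal(0.0, 4.0, size=(12, 2))
        y = np.where(X[:, 0] > 0, 1.0, -1.0)
        y[:2] = [1.0, -1.0]
        m = S.train_smo(X, y, S.SVMTrainingConfig(C=1.0, q=2, seed=1,
                                                  standardize=True))
        x = rng.normal(size=2)
        g = S.score_gradient(m, x)
        eps = 1e-6
        for i in range(2):
            e = np.zeros(2)
            e[i] = eps
            fd = (S.svm_score(m, x + e) - S.svm_score(m, x - e)) / (2 * eps)
            assert abs(fd - g[i]) < 1e-4 * max(1.0, abs(fd))

    def test_roundtrip_preserves_standardization(self, tmp_path, rng):
        X = rng.normal(2.0, 3.0, size=(14, 2))
        y = np.where(X.sum(axis=1) > 4.0, 1.0, -1.0)
        y[:2] = [1.0, -1.0]
        m = S.train_smo(X, y, S.SVMTrainingConfig(C=1.0, q=2, standardize=True))
        S.save_svm(m, tmp_path / "m.npz")
        back = S.load_svm(tmp_path / "m.npz")
        probe = rng.normal(2.0, 3.0, size=(5, 2))
        np.testing.assert_allclose(S.svm_score(back, probe), S.svm_score(m, probe))
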