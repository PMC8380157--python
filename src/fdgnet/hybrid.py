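"""Hybrid backbone + SVM model and its alternating end-to-end training.

The hybrid forward pass embeds a volume with the convolutional backbone,
scores the embedding with the frozen polynomial-kernel expansion
s(x) = sum_i w_i K(x, x_i) + b, and maps s through the two-way softmax head.
Because K is differentiable in x, cross-entropy on the head back-propagates
into the backbone while every SVM parameter stays fixed.

Training alternates:  supervised pretraining of the backbone with its
temporary FC head; an initial SMO fit on the resulting embeddings; then
repeated rounds of (a) fine-tuning the backbone through the frozen head and
(b) refitting the SVM on the fresh embeddings with the backbone frozen —
until the fine-tuning loss stabilizes or the round budget is exhausted.
No optimizer step ever updates backbone and SVM parameters together; the
round trace records parameter checksums before and after each phase so the
exclusivity is auditable.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import nn
from .backbone import (Backbone3D, BackboneConfig, TrainOptions, _stack,
                       build_backbone, extract_embeddings, load_backbone,
                       pretrain, save_backbone)
from .svm import (SVMModel, SVMTrainingConfig, head_loss_and_grad, load_svm,
                  save_svm, score_gradient, softmax_probs, svm_score, train_smo)
from .volumes_io import Dataset, Volume

# disease-severity order used to pick the positive class of a binary task
SEVERITY = {"NC": 0, "MCI": 1, "AD": 2}


def _svm_bytes(m: SVMModel) -> bytes:
    return (m.support_vectors.tobytes() + m.alphas.tobytes() + m.labels.tobytes()
            + np.float64(m.bias).tobytes() + bytes([m.q]))


def _digest(b: bytes) -> str:
    return hashlib.sha256(b).hexdigest()[:16]


@dataclass
class HybridModel:
    backbone: Backbone3D
    svm: SVMModel
    pos_label: str
    neg_label: str
    head_mode: str = "softmax"  # or "sign"

    def __post_init__(self) -> None:
        if self.svm.n_support and \
                self.svm.support_vectors.shape[1] != self.backbone.cfg.embedding_dim:
            raise ValueError(
                f"SVM dimension {self.svm.support_vectors.shape[1]} != backbone "
                f"embedding {self.backbone.cfg.embedding_dim}")
        if self.head_mode not in ("softmax", "sign"):
            raise ValueError("head_mode must be softmax|sign")

    # -- inference ---------------------------------------------------------
    def scores(self, data) -> np.ndarray:
        """Margin scores s for an iterable of samples (or a Dataset)."""
        emb = extract_embeddings(self.backbone, data)
        return np.atleast_1d(svm_score(self.svm, emb))

    def score_volume(self, v: Volume) -> float:
        emb = self.backbone.features(v.data[None, None], training=False)
        return float(svm_score(self.svm, emb)[0])

    def predict_volume(self, v: Volume) -> tuple[str, float]:
        """(class symbol, margin score) for one volume."""
        s = self.score_volume(v)
        return (self.pos_label if s >= 0 else self.neg_label), s

    def predict_proba(self, data) -> np.ndarray:
        """y0 = P(positive class) per sample via the softmax head."""
        return softmax_probs(self.scores(data))

    def predict_labels(self, data) -> list[str]:
        if self.head_mode == "sign":
            return [self.pos_label if s >= 0 else self.neg_label for s in self.scores(data)]
        return [self.pos_label if p >= 0.5 else self.neg_label
                for p in self.predict_proba(data)]

    def targets(self, data) -> np.ndarray:
        return np.array([1.0 if s.label == self.pos_label else 0.0 for s in data])

    def mean_loss(self, data) -> float:
        s = self.scores(data)
        loss, _ = head_loss_and_grad(s, self.targets(data))
        return loss / len(s)

    def accuracy(self, data) -> float:
        pred = self.predict_labels(data)
        return float(np.mean([p == s.label for p, s in zip(pred, data)]))


@dataclass
class AlternationConfig:
    rounds: int = 3
    finetune_epochs: int = 2
    convergence_tol: float = 1e-3
    use_verification_in_finetune: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rounds < 1:
            raise ValueError("rounds must be >= 1")
        if self.convergence_tol <= 0:
            raise ValueError("convergence_tol must be > 0")
        if self.finetune_epochs < 0:
            raise ValueError("finetune_epochs must be >= 0")


def infer_task_labels(data: Dataset) -> tuple[str, str]:
    """(positive, negative) for a binary dataset: the severer class is positive."""
    labels = sorted({s.label for s in data}, key=SEVERITY.get)
    if len(labels) != 2:
        raise ValueError(f"binary task needs exactly 2 classes, got {labels}")
    return labels[1], labels[0]


def attach_svm_head(backbone: Backbone3D, svm: SVMModel, pos_label: str = "AD",
                    neg_label: str = "NC") -> HybridModel:
    """Compose backbone and a trained SVM into one differentiable classifier."""
    return HybridModel(backbone=backbone, svm=svm, pos_label=pos_label,
                       neg_label=neg_label)


def finetune_backbone(h: HybridModel, data: Dataset, cfg: AlternationConfig,
                      opts: TrainOptions | None = None,
                      seed: int | None = None) -> list[float]:
    """Fine-tune backbone parameters through the frozen SVM head.

    Minimizes the mean softmax-head cross-entropy by SGD with the same
    4-batch gradient averaging as pretraining.  The SVM (support vectors,
    multipliers, bias) is bit-unchanged; the temporary FC head is not part
    of the optimized parameter set either.  Returns per-epoch mean loss.
    """
    if len(data) == 0:
        raise ValueError("empty dataset")
    opts = opts or TrainOptions()
    samples = list(data)
    p = h.targets(samples)
    rng = np.random.default_rng(h.backbone.seed + 1 if seed is None else seed)
    opt = nn.SGD(h.backbone.feature_parameter_layers(), lr=opts.lr,
                 momentum=opts.momentum)
    history: list[float] = []
    for epoch in range(cfg.finetune_epochs):
        opt.lr = opts.lr * opts.lr_decay ** epoch
        order = rng.permutation(len(samples))
        losses = []
        opt.zero_grad()
        pending = 0
        for start in range(0, len(order), opts.batch_size):
            idx = order[start:start + opts.batch_size]
            xb = _stack([samples[i] for i in idx])
            emb = h.backbone.features(xb, training=True)
            s = np.atleast_1d(svm_score(h.svm, emb))
            loss_sum, gs = head_loss_and_grad(s, p[idx])
            # chain: dL/demb = (dL/ds)/n * ds/demb, frozen kernel expansion
            gemb = (gs / len(idx))[:, None] * score_gradient(h.svm, emb)
            h.backbone.backward_from_embedding(gemb)
            losses.append(loss_sum / len(idx))
            pending += 1
            if pending == opts.accum_batches:
                opt.step(scale=1.0 / pending)
                opt.zero_grad()
                pending = 0
        if pending:
            opt.step(scale=1.0 / pending)
            opt.zero_grad()
        history.append(float(np.mean(losses)))
    return history


def refit_svm(h: HybridModel, data: Dataset, svm_cfg: SVMTrainingConfig) -> HybridModel:
    """Re-solve the SVM on current embeddings; the backbone is untouched."""
    emb = extract_embeddings(h.backbone, data)
    y = np.array([1.0 if s.label == h.pos_label else -1.0 for s in data])
    h.svm = train_smo(emb, y, svm_cfg)
    return h


def _check_disjoint_subjects(a: Dataset, b: Dataset) -> None:
    overlap = set(a.subjects()) & set(b.subjects())
    if overlap:
        raise ValueError(f"subject leakage between splits: {sorted(overlap)[:5]}")


def alternate_train(train_set: Dataset, verification_set: Dataset,
                    b_cfg: BackboneConfig, s_cfg: SVMTrainingConfig,
                    a_cfg: AlternationConfig,
                    pretrain_opts: TrainOptions | None = None,
                    finetune_opts: TrainOptions | None = None,
                    ) -> tuple[HybridModel, pd.DataFrame]:
    """Full alternating procedure for one binary task.

    1. pretrain the backbone (+FC head) on the training set;
    2. fit the initial SVM on the training-set embeddings;
    3. for up to ``rounds``: fine-tune the backbone through the frozen
       softmax head (on train plus verification if configured), then refit
       the SVM on fresh training-set embeddings; stop early when the
       relative change of the fine-tuning loss drops below
       ``convergence_tol``.

    Returns the hybrid model and a phase-by-phase trace (round, phase,
    loss, train accuracy, parameter checksums before/after each phase).
    """
    _check_disjoint_subjects(train_set, verification_set)
    pos, neg = infer_task_labels(train_set)
    pretrain_opts = pretrain_opts or TrainOptions()
    finetune_opts = finetune_opts or TrainOptions(lr=pretrain_opts.lr,
                                                 momentum=pretrain_opts.momentum)
    ss = np.random.SeedSequence(a_cfg.seed)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(3 + a_cfg.rounds)]

    backbone = build_backbone(b_cfg, seed=seeds[0])
    trace_rows = []

    y = np.array([1.0 if s.label == pos else -1.0 for s in train_set])

    def log(round_, phase, loss, svm, bb_before, svm_before, emb=None,
            n_epochs=None):
        """One trace row; training scores come from the current embeddings
        (computed at most once per phase) rather than fresh forward passes."""
        bb_after = _digest(backbone.parameter_bytes())
        svm_after = _digest(_svm_bytes(svm)) if svm is not None else ""
        if svm is not None and emb is not None:
            s = np.atleast_1d(svm_score(svm, emb))
            acc = float(np.mean((s >= 0) == (y == 1)))
            if loss is None:
                loss = head_loss_and_grad(s, (y == 1).astype(float))[0] / len(s)
        else:
            acc = np.nan
        trace_rows.append({
            "round": round_, "phase": phase, "loss": loss,
            "train_acc": acc, "n_epochs": n_epochs,
            "backbone_before": bb_before, "backbone_after": bb_after,
            "svm_before": svm_before, "svm_after": svm_after,
        })

    # Step (ii): supervised pretraining with the FC head
    bb_before = _digest(backbone.parameter_bytes())
    hist = pretrain(backbone, train_set, pretrain_opts, seed=seeds[1], pos_label=pos)
    log(0, "pretrain", hist[-1] if hist else np.nan, None, bb_before, "",
        n_epochs=len(hist))

    # Step (iii): initial SVM on the frozen embeddings
    emb = extract_embeddings(backbone, train_set)
    model = HybridModel(backbone=backbone, svm=train_smo(emb, y, s_cfg),
                        pos_label=pos, neg_label=neg)
    log(0, "initial_svm", None, model.svm,
        _digest(backbone.parameter_bytes()), "", emb)

    # Steps (iv)-(vi) repeated
    finetune_data = Dataset(list(train_set) + list(verification_set)) \
        if a_cfg.use_verification_in_finetune else train_set
    prev_loss = model.mean_loss(finetune_data)
    for rnd in range(1, a_cfg.rounds + 1):
        bb_before = _digest(backbone.parameter_bytes())
        svm_before = _digest(_svm_bytes(model.svm))
        hist = finetune_backbone(model, finetune_data, a_cfg, finetune_opts,
                                 seed=seeds[2 + rnd])
        ft_loss = hist[-1] if hist else model.mean_loss(finetune_data)
        assert _digest(_svm_bytes(model.svm)) == svm_before  # frozen contract
        emb = extract_embeddings(backbone, train_set)
        log(rnd, "finetune", ft_loss, model.svm, bb_before, svm_before, emb)

        bb_before = _digest(backbone.parameter_bytes())
        svm_before = _digest(_svm_bytes(model.svm))
        model.svm = train_smo(emb, y, s_cfg)  # Step (vi) on the same embeddings
        assert _digest(backbone.parameter_bytes()) == bb_before  # frozen contract
        log(rnd, "refit_svm", None, model.svm, bb_before, svm_before, emb)

        if abs(prev_loss - ft_loss) <= a_cfg.convergence_tol * max(abs(prev_loss), 1e-12):
            break
        prev_loss = ft_loss
    return model, pd.DataFrame(trace_rows)


def desk_svm_config(seed: int = 0) -> SVMTrainingConfig:
    """SVM settings for desk-scale phantom experiments (larger penalty C:
    the low-dimensional desk embeddings need a harder margin)."""
    return SVMTrainingConfig(C=10.0, q=2, seed=seed)


def desk_schedule(seed: int = 0, rounds: int = 2):
    """Training schedule used for desk-scale phantom experiments.

    Momentum-SGD (0.9), lr 1e-2, pretraining until two consecutive epochs
    fit the training set (accuracy >= 0.98; minimum 4, maximum 12 epochs),
    then lr 1e-3 for one fine-tuning epoch per alternation round — enough
    for the backbone to converge on the strongly separable phantom cohorts
    while a full binary run stays around a minute of CPU.  Pairs with an
    SVM penalty of C=10 (see ``desk_svm_config``).
    Returns (pretrain_opts, finetune_opts, alternation_cfg).
    """
    return (TrainOptions(epochs=12, lr=1e-2, momentum=0.9, min_epochs=4,
                         stop_acc=0.98, lr_decay=0.85),
            TrainOptions(lr=1e-3, momentum=0.9),
            AlternationConfig(rounds=rounds, finetune_epochs=1, seed=seed))


# -- checkpoint bundles ----------------------------------------------------

def save_bundle(model: HybridModel, trace: pd.DataFrame | None, out_dir) -> Path:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    save_backbone(model.backbone, out_dir / "backbone.npz")
    save_svm(model.svm, out_dir / "svm.npz")
    (out_dir / "task.txt").write_text(f"{model.pos_label},{model.neg_label}\n")
    if trace is not None:
        trace.to_csv(out_dir / "trace.csv", index=False)
    return out_dir


def load_bundle(bundle_dir) -> HybridModel:
    bundle_dir = Path(bundle_dir)
    pos, neg = (bundle_dir / "task.txt").read_text().strip().split(",")
    return HybridModel(backbone=load_backbone(bundle_dir / "backbone.npz"),
                       svm=load_svm(bundle_dir / "svm.npz"),
                       pos_label=pos, neg_label=neg)
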