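"""Metrics, ROC/AUC and subject-grouped cross-validation.

Binary metrics follow the confusion-count definitions ACC = (TP+TN)/total,
SEN = TP/(TP+FN), SPE = TN/(TN+FP); undefined denominators yield None, not
zero.  AUC is the midrank Mann-Whitney statistic (equal to the trapezoidal
area under the ROC over all thresholds, ties counted half).

Cross-validation is five-fold at subject granularity, stratified by class:
every subject's scans fall in exactly one of {train, verification, test}
per rotation, the test part rotates through the folds and the verification
part is the next fold in rotation order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .volumes_io import Dataset


@dataclass
class ConfusionCounts:
    TP: int
    FP: int
    TN: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.FP, self.TN, self.FN) < 0:
            raise ValueError("counts must be non-negative")
        if self.TP + self.FP + self.TN + self.FN == 0:
            raise ValueError("empty confusion table")


@dataclass
class MetricSet:
    acc: float | None = None
    sen: float | None = None
    spe: float | None = None
    auc: float | None = None


def binary_metrics(c: ConfusionCounts) -> MetricSet:
    """ACC/SEN/SPE from counts; a zero denominator leaves the metric None."""
    total = c.TP + c.TN + c.FP + c.FN
    acc = (c.TP + c.TN) / total
    sen = c.TP / (c.TP + c.FN) if c.TP + c.FN else None
    spe = c.TN / (c.TN + c.FP) if c.TN + c.FP else None
    return MetricSet(acc=acc, sen=sen, spe=spe)


def confusion_from_predictions(y_true, y_pred, positive) -> ConfusionCounts:
    t = np.asarray([y == positive for y in y_true])
    p = np.asarray([y == positive for y in y_pred])
    return ConfusionCounts(TP=int((t & p).sum()), FP=int((~t & p).sum()),
                           TN=int((~t & ~p).sum()), FN=int((t & ~p).sum()))


def roc_auc(scores, labels) -> float:
    """Area under the ROC via the midrank Mann-Whitney formulation.

    ``labels`` are +-1 (or truthy positives); both classes must be present.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    pos = y == 1 if set(np.unique(y)) <= {-1, 1} else y.astype(bool)
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC undefined with a single class")
    r = rankdata(s)  # midranks handle ties as half-wins
    return float((r[pos].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def roc_curve_points(scores, labels) -> pd.DataFrame:
    """(threshold, FPR, TPR) at every distinct score, for CSV export."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    pos = y == 1 if set(np.unique(y)) <= {-1, 1} else y.astype(bool)
    order = np.argsort(-s, kind="stable")
    tps = np.cumsum(pos[order])
    fps = np.cumsum(~pos[order])
    keep = np.r_[np.flatnonzero(np.diff(s[order]) != 0), len(s) - 1]
    rows = {"threshold": s[order][keep],
            "fpr": fps[keep] / max(fps[-1], 1), "tpr": tps[keep] / max(tps[-1], 1)}
    df = pd.DataFrame(rows)
    df.loc[-1] = [np.inf, 0.0, 0.0]
    return df.sort_index().reset_index(drop=True)


@dataclass
class FoldAssignment:
    fold_of_subject: dict  # subject_id -> fold index

    def fold_subjects(self, k: int) -> list[list[str]]:
        folds = [[] for _ in range(k)]
        for sid, f in self.fold_of_subject.items():
            folds[f].append(sid)
        return folds


def assign_folds(d: Dataset, k: int = 5, seed: int = 0) -> FoldAssignment:
    """Stratified subject-level fold assignment (fold sizes within 1 per class)."""
    by_class: dict[str, list[str]] = {}
    for sid, label in sorted(d.subjects().items()):
        by_class.setdefault(label, []).append(sid)
    rng = np.random.default_rng(seed)
    assignment = {}
    for label in sorted(by_class):
        sids = by_class[label]
        if len(sids) < k:
            raise ValueError(f"class {label} has {len(sids)} subjects < {k} folds")
        perm = rng.permutation(len(sids))
        for pos, idx in enumerate(perm):
            assignment[sids[idx]] = pos % k
    return FoldAssignment(assignment)


def grouped_kfold(d: Dataset, k: int = 5, seed: int = 0) -> list[tuple[list, list, list]]:
    """k rotations of (train, verification, test) subject-ID lists.

    Rotation r: test = fold r, verification = fold (r+1) mod k, train = the
    remaining k-2 folds.  Splits are at subject granularity, stratified by
    class, so no subject's scans ever straddle two roles.
    """
    fa = assign_folds(d, k, seed)
    folds = fa.fold_subjects(k)
    rotations = []
    for r in range(k):
        test = sorted(folds[r])
        verif = sorted(folds[(r + 1) % k])
        train = sorted(sid for f in range(k) if f not in (r, (r + 1) % k)
                       for sid in folds[f])
        rotations.append((train, verif, test))
    return rotations


def grouped_holdout_split(d: Dataset, seed: int = 0, test_frac: float = 0.2,
                          verif_frac: float = 0.2):
    """Single stratified (train, verification, test) split at subject level.

    Fractions apply per class to subject counts (rounded, at least one
    subject each); the remainder trains.
    """
    rng = np.random.default_rng(seed)
    by_class: dict[str, list[str]] = {}
    for sid, lab in sorted(d.subjects().items()):
        by_class.setdefault(lab, []).append(sid)
    train, verif, test = [], [], []
    for lab in sorted(by_class):
        sids = by_class[lab]
        if len(sids) < 3:
            raise ValueError(f"class {lab} needs >= 3 subjects to split")
        perm = [sids[i] for i in rng.permutation(len(sids))]
        n_test = max(1, round(test_frac * len(sids)))
        n_verif = max(1, round(verif_frac * len(sids)))
        test += perm[:n_test]
        verif += perm[n_test:n_test + n_verif]
        train += perm[n_test + n_verif:]
    return d.subset(train), d.subset(verif), d.subset(test)


def three_class_report(confusion: np.ndarray,
                       classes=("AD", "MCI", "NC")) -> dict:
    """Per-class recall (diagonal over row sum) and their unweighted mean.

    Rows are true classes, columns predicted.  An empty row leaves that
    class None and excludes it from the average.
    """
    m = np.asarray(confusion, dtype=float)
    if m.shape != (3, 3):
        raise ValueError("confusion matrix must be 3x3")
    out = {}
    vals = []
    for i, cls in enumerate(classes):
        row = m[i].sum()
        out[cls] = float(m[i, i] / row) if row else None
        if row:
            vals.append(out[cls])
    out["average"] = float(np.mean(vals)) if vals else None
    return out


def confusion_3x3(y_true, y_pred, classes=("AD", "MCI", "NC")) -> np.ndarray:
    idx = {c: i for i, c in enumerate(classes)}
    m = np.zeros((3, 3), dtype=int)
    for t, p in zip(y_true, y_pred):
        m[idx[t], idx[p]] += 1
    return m


def evaluate_binary(model, data: Dataset) -> MetricSet:
    """ACC/SEN/SPE/AUC of a hybrid binary model on a labeled dataset."""
    scores = model.scores(data)
    y_true = [s.label for s in data]
    y_pred = [model.pos_label if v >= 0 else model.neg_label for v in scores]
    ms = binary_metrics(confusion_from_predictions(y_true, y_pred, model.pos_label))
    truth = np.array([1 if t == model.pos_label else -1 for t in y_true])
    if len(set(truth)) == 2:
        ms.auc = roc_auc(scores, truth)
    return ms


def cross_validate(d: Dataset, train_fn, eval_fn, k: int = 5,
                   seed: int = 0) -> pd.DataFrame:
    """Generic grouped k-fold driver.

    ``train_fn(train, verification, fold_seed)`` returns a fitted object;
    ``eval_fn(fitted, split_dataset)`` returns a metric dict.  Metrics are
    reported per fold for both the train and test splits, plus a mean row.
    """
    rotations = grouped_kfold(d, k, seed)
    ss = np.random.SeedSequence(seed)
    fold_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(k)]
    rows = []
    for fold, (train_ids, verif_ids, test_ids) in enumerate(rotations):
        train, verif, test = d.subset(train_ids), d.subset(verif_ids), d.subset(test_ids)
        fitted = train_fn(train, verif, fold_seeds[fold])
        for split_name, split in (("train", train), ("test", test)):
            rows.append({"fold": fold, "split": split_name,
                         **eval_fn(fitted, split)})
    df = pd.DataFrame(rows)
    means = df.groupby("split").mean(numeric_only=True).drop(columns=["fold"])
    for split_name, mean_row in means.iterrows():
        rows.append({"fold": "mean", "split": split_name, **mean_row.to_dict()})
    return pd.DataFrame(rows)
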