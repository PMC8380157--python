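"""Three-way decision fusion over the pairwise binary classifiers.

The 3-class NC/MCI/AD problem is solved one-vs-one: three hybrid models
handle AD vs NC, MCI vs NC and AD vs MCI (the severer class is the positive
pole of each machine).  Fusion of the three decisions:

  (1) if any class is predicted by at least two machines, it wins (majority);
  (2) if all three decisions differ, the machine with the largest absolute
      margin score |s_i| decides; exact ties break by the fixed task order
      AD_NC < MCI_NC < AD_MCI.

Only 2 of the 8 possible decision patterns lack a majority, so the margin
rule is the rare path.  Raw scores are compared across machines without
normalization by default; an optional per-model standardization (divide by
the training-set score SD) is available since the three score scales are
not calibrated to each other.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .hybrid import HybridModel
from .volumes_io import Dataset, Volume

TASK_ORDER = ("AD_NC", "MCI_NC", "AD_MCI")


@dataclass(frozen=True)
class BinaryTaskSpec:
    name: str
    positive: str
    negative: str

    def __post_init__(self) -> None:
        if self.positive == self.negative:
            raise ValueError("positive and negative classes must differ")


TASKS = {
    "AD_NC": BinaryTaskSpec("AD_NC", positive="AD", negative="NC"),
    "MCI_NC": BinaryTaskSpec("MCI_NC", positive="MCI", negative="NC"),
    "AD_MCI": BinaryTaskSpec("AD_MCI", positive="AD", negative="MCI"),
}


@dataclass
class TriPrediction:
    """Per-task decisions and raw margin scores, in TASK_ORDER."""

    decisions: dict  # task name -> class symbol
    scores: dict     # task name -> s

    def __post_init__(self) -> None:
        for t in TASK_ORDER:
            if t not in self.decisions or t not in self.scores:
                raise ValueError(f"missing task {t}")
            task = TASKS[t]
            if self.decisions[t] not in (task.positive, task.negative):
                raise ValueError(f"decision {self.decisions[t]!r} invalid for {t}")
            if not np.isfinite(self.scores[t]):
                raise ValueError("scores must be finite")


@dataclass
class FinalDecision:
    label: str
    rule: str  # "majority" | "max_margin"
    winning_task: str | None = None


def tie_break(scores) -> int:
    """Index of the largest |s|; exact ties take the earliest task in order."""
    a = np.abs(np.asarray(scores, dtype=float))
    return int(np.argmax(a))  # argmax returns the first maximal index


def fuse(t: TriPrediction) -> FinalDecision:
    """Majority vote over the three binary decisions, margin rule otherwise."""
    votes = [t.decisions[name] for name in TASK_ORDER]
    for label in set(votes):
        if votes.count(label) >= 2:
            return FinalDecision(label=label, rule="majority")
    k = tie_break([t.scores[name] for name in TASK_ORDER])
    win = TASK_ORDER[k]
    return FinalDecision(label=t.decisions[win], rule="max_margin", winning_task=win)


def _check_models(models: dict) -> None:
    for name in TASK_ORDER:
        if name not in models:
            raise ValueError(f"missing model for task {name}")
        task, m = TASKS[name], models[name]
        if (m.pos_label, m.neg_label) != (task.positive, task.negative):
            raise ValueError(
                f"model for {name} maps ({m.pos_label},{m.neg_label}), "
                f"expected ({task.positive},{task.negative})")


def classify_three_way(v: Volume, models: dict[str, HybridModel],
                       score_scale: dict[str, float] | None = None,
                       ) -> tuple[FinalDecision, TriPrediction]:
    """Run the three hybrids on one volume and fuse their decisions.

    ``score_scale`` optionally divides each machine's score by its
    training-set score SD before the margin comparison (off by default).
    """
    _check_models(models)
    decisions, scores = {}, {}
    for name in TASK_ORDER:
        label, s = models[name].predict_volume(v)
        if score_scale:
            s = s / score_scale[name]
        decisions[name] = label
        scores[name] = s
    tri = TriPrediction(decisions=decisions, scores=scores)
    return fuse(tri), tri


def predict_dataset(data: Dataset, models: dict[str, HybridModel],
                    score_scale: dict[str, float] | None = None) -> pd.DataFrame:
    """Fusion report: one row per scan with per-task evidence and fused label.

    Scores every scan through each machine in batches (same values as
    per-volume ``classify_three_way``, one embedding pass per model).
    """
    _check_models(models)
    samples = list(data)
    per_task = {}
    for name in TASK_ORDER:
        m = models[name]
        scores = np.atleast_1d(m.scores(samples)).astype(float)
        if score_scale:
            scores = scores / score_scale[name]
        decisions = [m.pos_label if v >= 0 else m.neg_label for v in scores]
        per_task[name] = (decisions, scores)
    rows = []
    for i, s in enumerate(samples):
        tri = TriPrediction(
            decisions={n: per_task[n][0][i] for n in TASK_ORDER},
            scores={n: float(per_task[n][1][i]) for n in TASK_ORDER})
        final = fuse(tri)
        row = {"scan_id": s.scan_id, "subject_id": s.subject_id, "true_label": s.label}
        for name in TASK_ORDER:
            row[f"{name}_decision"] = tri.decisions[name]
            row[f"{name}_score"] = tri.scores[name]
        row.update({"fused_label": final.label, "rule": final.rule,
                    "winning_task": final.winning_task or ""})
        rows.append(row)
    return pd.DataFrame(rows)
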