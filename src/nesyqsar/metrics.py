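"""Binary-classification metrics: accuracy, F1, ROC-AUC, MCC, confusion counts.

Accuracy, F1 and MCC are computed directly from the confusion counts by their
defining formulas; ROC-AUC is computed as the Mann-Whitney rank statistic
(ties counted half), which equals the area under the TPR-vs-FPR curve.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.stats import rankdata

__all__ = [
    "ConfusionCounts",
    "EvalReport",
    "confusion_counts",
    "accuracy",
    "f1_score",
    "mcc",
    "roc_auc",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def confusion_counts(y_true: np.ndarray, y_pred: np.ndarray, positive: int = 1) -> ConfusionCounts:
    """Confusion counts with ``positive`` as the positive class index."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("label/prediction shape mismatch")
    t = y_true == positive
    p = y_pred == positive
    return ConfusionCounts(
        tp=int(np.sum(t & p)),
        tn=int(np.sum(~t & ~p)),
        fp=int(np.sum(~t & p)),
        fn=int(np.sum(t & ~p)),
    )


def accuracy(counts: ConfusionCounts) -> float:
    """(TP + TN) / (TP + TN + FP + FN)."""
    if counts.total == 0:
        raise ValueError("empty confusion matrix")
    return (counts.tp + counts.tn) / counts.total


def f1_score(counts: ConfusionCounts) -> float:
    """Harmonic mean of precision and recall; defined 0 when both vanish."""
    denom = 2 * counts.tp + counts.fp + counts.fn
    if denom == 0:
        return 0.0
    return 2 * counts.tp / denom


def mcc(counts: ConfusionCounts) -> float:
    """Matthews correlation coefficient; defined 0 on a degenerate margin."""
    tp, tn, fp, fn = counts.tp, counts.tn, counts.fp, counts.fn
    denom = math.sqrt(float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    if denom == 0.0:
        return 0.0
    return (tp * tn - fp * fn) / denom


def roc_auc(scores: np.ndarray, labels: np.ndarray, positive: int = 1) -> float:
    """Area under the ROC curve via the rank (Mann-Whitney U) statistic.

    Equivalent to the probability that a random positive outranks a random
    negative, with ties counted half.
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    pos = labels == positive
    n_pos = int(pos.sum())
    n_neg = int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC-AUC requires both classes present")
    ranks = rankdata(scores)
    u = ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


@dataclass
class EvalReport:
    """Confusion counts plus the four headline metrics and training history."""

    counts: ConfusionCounts
    accuracy: float
    f1: float
    roc_auc: float
    mcc: float
    history: dict[str, list[float]] = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["counts"] = asdict(self.counts)
        return d

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_scores(
        cls,
        y_true: np.ndarray,
        positive_scores: np.ndarray,
        threshold: float = 0.5,
        positive: int = 1,
        history: dict[str, list[float]] | None = None,
    ) -> "EvalReport":
        y_pred = np.where(np.asarray(positive_scores) >= threshold, positive, 1 - positive)
        counts = confusion_counts(y_true, y_pred, positive=positive)
        return cls(
            counts=counts,
            accuracy=accuracy(counts),
            f1=f1_score(counts),
            roc_auc=roc_auc(positive_scores, y_true, positive=positive),
            mcc=mcc(counts),
            history=history or {},
        )
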