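"""Binary classification metrics for the detection experiments.

The patient class (label 1) is the positive class.  Seven metrics are
reported: accuracy, precision, recall, F1, sensitivity, specificity and
AUC.  Recall and sensitivity are by definition the same quantity (the
positive-class recall); both fields are emitted because the reporting
schema lists both.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict

import numpy as np
from scipy.stats import rankdata

METRIC_NAMES = ("accuracy", "precision", "recall", "f1",
                "sensitivity", "specificity", "auc")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self):
        for name in ("tp", "fn", "fp", "tn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.fp + self.tn


@dataclass(frozen=True)
class MetricRecord:
    accuracy: float
    precision: float
    recall: float
    f1: float
    sensitivity: float
    specificity: float
    auc: float
    confusion: ConfusionCounts

    def to_dict(self) -> dict:
        d = asdict(self)
        d["confusion"] = asdict(self.confusion)
        return d

    def values(self) -> dict[str, float]:
        return {k: getattr(self, k) for k in METRIC_NAMES}


def _ratio(num: float, den: float, name: str) -> float:
    if den == 0:
        warnings.warn(f"{name} has zero denominator; reporting 0")
        return 0.0
    return num / den


def auc_score(scores: np.ndarray, labels: np.ndarray) -> float:
    """Rank-statistic AUC (Mann-Whitney) with 0.5 credit for ties.

    Returns NaN with a warning when only one class is present.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        warnings.warn("AUC undefined for a one-class label vector; returning NaN")
        return float("nan")
    ranks = rankdata(scores)  # average ranks give the 0.5 tie credit
    r_pos = ranks[labels == 1].sum()
    return float((r_pos - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def metrics_from_counts(counts: ConfusionCounts, auc: float = float("nan")) -> MetricRecord:
    tp, fn, fp, tn = counts.tp, counts.fn, counts.fp, counts.tn
    precision = _ratio(tp, tp + fp, "precision")
    recall = _ratio(tp, tp + fn, "recall")
    f1 = _ratio(2 * precision * recall, precision + recall, "f1")
    return MetricRecord(
        accuracy=_ratio(tp + tn, counts.total, "accuracy"),
        precision=precision,
        recall=recall,
        f1=f1,
        sensitivity=recall,
        specificity=_ratio(tn, tn + fp, "specificity"),
        auc=auc,
        confusion=counts,
    )


def compute_metrics(scores: np.ndarray, labels: np.ndarray,
                    threshold: float = 0.5) -> MetricRecord:
    """Seven metrics from per-sample positive-class probabilities.

    ``scores`` in [0, 1]; hard labels via ``score >= threshold``.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have the same shape")
    if scores.size == 0:
        raise ValueError("empty score vector")
    if scores.min() < 0.0 or scores.max() > 1.0:
        raise ValueError("scores must lie in [0, 1]")
    pred = (scores >= threshold).astype(int)
    counts = ConfusionCounts(
        tp=int(((pred == 1) & (labels == 1)).sum()),
        fn=int(((pred == 0) & (labels == 1)).sum()),
        fp=int(((pred == 1) & (labels == 0)).sum()),
        tn=int(((pred == 0) & (labels == 0)).sum()),
    )
    return metrics_from_counts(counts, auc=auc_score(scores, labels))
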