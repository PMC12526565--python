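"""Confusion-count metrics, ROC/AUC, fold confidence intervals, paired tests.

Ratios with zero denominators are reported as ``nan`` (the explicit
"undefined" marker), never silently as 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve as _roc_curve

__all__ = [
    "ConfusionCounts", "IntervalEstimate",
    "metrics_from_counts", "roc_auc", "fold_ci", "paired_t",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0

    def __post_init__(self):
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.tp + other.tp, self.fp + other.fp,
                               self.tn + other.tn, self.fn + other.fn)


def _ratio(num: float, den: float) -> float:
    return num / den if den > 0 else float("nan")


def metrics_from_counts(counts: ConfusionCounts) -> dict[str, float]:
    """Accuracy, precision, recall (sensitivity), specificity, F1 and FPR."""
    if counts.total == 0:
        raise ValueError("no evaluated items")
    tp, fp, tn, fn = counts.tp, counts.fp, counts.tn, counts.fn
    precision = _ratio(tp, tp + fp)
    recall = _ratio(tp, tp + fn)
    if np.isnan(precision) or np.isnan(recall) or precision + recall == 0:
        f1 = float("nan")
    else:
        f1 = 2 * precision * recall / (precision + recall)
    return {
        "accuracy": _ratio(tp + tn, counts.total),
        "precision": precision,
        "recall": recall,
        "specificity": _ratio(tn, tn + fp),
        "f1": f1,
        "fpr": _ratio(fp, fp + tn),
    }


def roc_auc(scores, labels) -> tuple[float, np.ndarray, np.ndarray]:
    """AUC by threshold sweep; returns (auc, fpr_points, tpr_points).

    Equals the rank statistic: the probability that a random positive
    outscores a random negative, with ties counted one half.
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels).astype(int)
    if len(scores) != len(labels):
        raise ValueError("scores and labels must align")
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present")
    fpr, tpr, _ = _roc_curve(labels, scores)
    return float(_trapezoid_auc(fpr, tpr)), fpr, tpr


@dataclass(frozen=True)
class IntervalEstimate:
    """Two-sided 95% Student-t interval over per-fold values."""

    mean: float
    sd: float
    n: int
    half_width: float
    t_critical: float

    @property
    def lo(self) -> float:
        return self.mean - self.half_width

    @property
    def hi(self) -> float:
        return self.mean + self.half_width


def fold_ci(values, confidence: float = 0.95) -> IntervalEstimate:
    """mean ± t_{1-(1-conf)/2, n-1} * s / sqrt(n) over per-fold values."""
    values = np.asarray(values, dtype=np.float64)
    if len(values) < 2:
        raise ValueError("need at least 2 folds")
    n = len(values)
    mean = float(values.mean())
    sd = float(values.std(ddof=1))
    t_crit = float(stats.t.ppf(0.5 + confidence / 2, df=n - 1))
    return IntervalEstimate(mean=mean, sd=sd, n=n,
                            half_width=t_crit * sd / np.sqrt(n),
                            t_critical=t_crit)


def paired_t(values_a, values_b) -> dict:
    """Classic paired two-sided t-test over fold values (df = n-1).

    A zero-variance difference vector is reported as a degenerate result
    (``degenerate=True``, statistic/p nan) rather than a division by zero.
    """
    a = np.asarray(values_a, dtype=np.float64)
    b = np.asarray(values_b, dtype=np.float64)
    if a.shape != b.shape or len(a) < 2:
        raise ValueError("need two equal-length samples of size >= 2")
    d = a - b
    if np.allclose(d.std(ddof=1), 0.0):
        return {"statistic": float("nan"), "p_value": float("nan"),
                "df": len(d) - 1, "degenerate": True,
                "mean_difference": float(d.mean())}
    res = stats.ttest_rel(a, b)
    return {"statistic": float(res.statistic), "p_value": float(res.pvalue),
            "df": len(d) - 1, "degenerate": False,
            "mean_difference": float(d.mean())}
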