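"""Evaluation metrics for PSM classification.

Scalar metrics from the confusion table (accuracy, sensitivity,
specificity, precision and the class-balance-insensitive net prediction =
(sensitivity + specificity) / 2), plus threshold-sweep curves: the ROC as
the (1 - specificity, sensitivity) curve with trapezoidal AUC, and the
precision-recall curve.  Tied scores are grouped into a single threshold
step (the Mann-Whitney half-credit convention), so the AUC equals the
pairwise rank-sum statistic exactly.  Metrics with a zero denominator are
reported as NaN and flagged by name, never silently as 0 or 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from sklearn import metrics as _skm


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class MetricsReport:
    accuracy: float
    sensitivity: float
    specificity: float
    net_prediction: float
    precision: float
    undefined: set[str] = field(default_factory=set)
    auc: float | None = None
    roc_points: np.ndarray | None = None
    prc_points: np.ndarray | None = None

    def scalars(self) -> dict[str, float]:
        out = {"accuracy": self.accuracy, "sensitivity": self.sensitivity,
               "specificity": self.specificity,
               "net_prediction": self.net_prediction,
               "precision": self.precision}
        if self.auc is not None:
            out["auc"] = self.auc
        return out


def confusion(labels, predictions) -> ConfusionCounts:
    """Cross-tabulate binary labels against binary predictions (1 = positive)."""
    y = np.asarray(labels)
    p = np.asarray(predictions)
    if y.shape != p.shape or y.ndim != 1:
        raise ValueError("labels and predictions must be equal-length vectors")
    if y.size == 0:
        raise ValueError("empty input")
    return ConfusionCounts(
        tp=int(((y == 1) & (p == 1)).sum()),
        fp=int(((y == 0) & (p == 1)).sum()),
        tn=int(((y == 0) & (p == 0)).sum()),
        fn=int(((y == 1) & (p == 0)).sum()),
    )


def net_prediction(sensitivity: float, specificity: float) -> float:
    """(sensitivity + specificity) / 2."""
    return (sensitivity + specificity) / 2


def metrics(counts: ConfusionCounts) -> MetricsReport:
    """Scalar metrics from confusion counts, with undefined-metric flags."""
    if counts.total == 0:
        raise ValueError("no instances")
    undefined: set[str] = set()

    def ratio(num: int, den: int, name: str) -> float:
        if den == 0:
            undefined.add(name)
            return math.nan
        return num / den

    acc = (counts.tp + counts.tn) / counts.total
    sens = ratio(counts.tp, counts.tp + counts.fn, "sensitivity")
    spec = ratio(counts.tn, counts.tn + counts.fp, "specificity")
    prec = ratio(counts.tp, counts.tp + counts.fp, "precision")
    if "sensitivity" in undefined or "specificity" in undefined:
        undefined.add("net_prediction")
        netp = math.nan
    else:
        netp = net_prediction(sens, spec)
    return MetricsReport(accuracy=acc, sensitivity=sens, specificity=spec,
                         net_prediction=netp, precision=prec,
                         undefined=undefined)


def roc_auc(scores, labels) -> tuple[np.ndarray, float]:
    """ROC points and trapezoidal AUC over all distinct-score thresholds.

    Returns an (m, 2) array of (1 - specificity, sensitivity) points
    starting at (0, 0) and ending at (1, 1), and the area under it.
    """
    y = np.asarray(labels)
    s = np.asarray(scores, dtype=float)
    if y.shape != s.shape:
        raise ValueError("scores and labels must have equal length")
    if len(set(np.unique(y))) < 2:
        raise ValueError("ROC requires both classes")
    fpr, tpr, _ = _skm.roc_curve(y, s, drop_intermediate=False)
    points = np.column_stack([fpr, tpr])
    auc = float(np.trapezoid(tpr, fpr))
    return points, auc


def prc(scores, labels) -> np.ndarray:
    """Precision-recall points at each distinct-score threshold.

    Returns an (m, 2) array of (recall, precision) with recall
    non-decreasing along the sweep from the strictest threshold down.
    """
    y = np.asarray(labels)
    s = np.asarray(scores, dtype=float)
    if y.shape != s.shape:
        raise ValueError("scores and labels must have equal length")
    if (y == 1).sum() == 0:
        raise ValueError("PRC requires at least one positive")
    precision, recall, _ = _skm.precision_recall_curve(y, s)
    # sklearn orders from the loosest to the strictest threshold and appends
    # a synthetic (recall=0, precision=1) endpoint; drop it and flip so the
    # sweep runs strictest -> loosest with recall non-decreasing.
    precision, recall = precision[:-1], recall[:-1]
    return np.column_stack([recall, precision])[::-1]


def evaluate_scores(scores, labels, threshold: float = 0.0) -> MetricsReport:
    """Full report: threshold the scores for the confusion-based metrics
    (strictly greater than ``threshold`` is a positive call, matching the
    margin > 0 rule; use 0.5 for calibrated probabilities) and sweep them
    for the ROC/AUC and PRC."""
    y = np.asarray(labels)
    s = np.asarray(scores, dtype=float)
    report = metrics(confusion(y, (s > threshold).astype(int)))
    report.roc_points, report.auc = roc_auc(s, y)
    report.prc_points = prc(s, y)
    return report
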