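"""Binary-classification performance measures.

Implements the metric suite conventional in antifreeze-protein
prediction work: from the confusion counts TP/FP/TN/FN,

    precision   = TP / (TP + FP)
    specificity = TN / (TN + FP)
    recall      = TP / (TP + FN)
    accuracy    = (TP + TN) / (TP + FP + TN + FN)
    MCC         = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))

plus Youden's index (recall + specificity - 1) at the operating
threshold, and the ROC curve (false-positive rate vs. true-positive
rate over descending score thresholds, ties grouped) with trapezoidal
AUC.  Any metric whose denominator is zero is reported as NaN — an
explicit undefined marker, never silently 0 — so degenerate folds stay
visible in reports.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.metrics import roc_curve

__all__ = [
    "UNDEFINED",
    "ConfusionCounts",
    "MetricsReport",
    "confusion",
    "scalar_metrics",
    "roc_and_auc",
    "evaluate",
]

#: Marker returned for a metric whose denominator is zero.
UNDEFINED = math.nan


class MetricsError(ValueError):
    pass


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.tp + other.tp, self.fp + other.fp,
                               self.tn + other.tn, self.fn + other.fn)


def confusion(labels: Sequence[int], predictions: Sequence[int]) -> ConfusionCounts:
    """Exact confusion counts from binary labels and binary predictions."""
    y = np.asarray(labels, dtype=int)
    p = np.asarray(predictions, dtype=int)
    if y.shape != p.shape or y.ndim != 1:
        raise MetricsError(f"shape mismatch: labels {y.shape}, predictions {p.shape}")
    if y.size == 0:
        raise MetricsError("cannot evaluate an empty prediction set")
    return ConfusionCounts(
        tp=int(((y == 1) & (p == 1)).sum()),
        fp=int(((y == 0) & (p == 1)).sum()),
        tn=int(((y == 0) & (p == 0)).sum()),
        fn=int(((y == 1) & (p == 0)).sum()),
    )


def _ratio(num: float, den: float) -> float:
    return num / den if den else UNDEFINED


def scalar_metrics(counts: ConfusionCounts) -> dict[str, float]:
    """Evaluate the scalar formulas; zero denominators yield NaN."""
    if counts.total < 1:
        raise MetricsError("empty confusion matrix")
    tp, fp, tn, fn = counts.tp, counts.fp, counts.tn, counts.fn
    precision = _ratio(tp, tp + fp)
    specificity = _ratio(tn, tn + fp)
    recall = _ratio(tp, tp + fn)
    accuracy = _ratio(tp + tn, counts.total)
    mcc_den = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    mcc = _ratio(tp * tn - fp * fn, mcc_den)
    youden = recall + specificity - 1  # NaN-propagating by construction
    return {
        "precision": precision,
        "specificity": specificity,
        "recall": recall,
        "accuracy": accuracy,
        "mcc": mcc,
        "youden": youden,
    }


def roc_and_auc(
    labels: Sequence[int], scores: Sequence[float]
) -> tuple[list[tuple[float, float]], float]:
    """ROC points ((0,0) ... (1,1), ties grouped) and trapezoidal AUC."""
    y = np.asarray(labels, dtype=int)
    s = np.asarray(scores, dtype=float)
    if y.shape != s.shape or y.ndim != 1:
        raise MetricsError("labels and scores must be 1-d and equal length")
    if len(np.unique(y)) < 2:
        raise MetricsError("AUC undefined: only one class present")
    fpr, tpr, _ = roc_curve(y, s, drop_intermediate=False)
    points = list(zip(fpr.tolist(), tpr.tolist()))
    if points[0] != (0.0, 0.0):
        points.insert(0, (0.0, 0.0))
    if points[-1] != (1.0, 1.0):
        points.append((1.0, 1.0))
    auc = float(np.trapezoid([t for _, t in points], [f for f, _ in points]))
    return points, auc


@dataclass
class MetricsReport:
    """Confusion counts, the scalar metric suite and the ROC curve."""

    counts: ConfusionCounts
    precision: float
    specificity: float
    recall: float
    accuracy: float
    mcc: float
    youden: float
    auc: float = UNDEFINED
    roc_points: list[tuple[float, float]] = field(default_factory=list)

    SCALAR_FIELDS = ("accuracy", "precision", "recall", "specificity",
                     "mcc", "auc", "youden")

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in self.SCALAR_FIELDS}
        d.update(tp=self.counts.tp, fp=self.counts.fp,
                 tn=self.counts.tn, fn=self.counts.fn)
        return d

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump({k: (None if isinstance(v, float) and math.isnan(v) else v)
                       for k, v in self.to_dict().items()}, fh, indent=2)

    def tsv_row(self) -> str:
        return "\t".join(
            f"{getattr(self, k):.4f}" if not math.isnan(getattr(self, k)) else "NA"
            for k in self.SCALAR_FIELDS
        )

    def roc_csv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("fpr,tpr\n")
            for f, t in self.roc_points:
                fh.write(f"{f},{t}\n")


def evaluate(
    labels: Sequence[int],
    scores: Sequence[float],
    threshold: float = 0.5,
) -> MetricsReport:
    """Full report from probability scores at a decision threshold."""
    y = np.asarray(labels, dtype=int)
    s = np.asarray(scores, dtype=float)
    counts = confusion(y, (s >= threshold).astype(int))
    scalars = scalar_metrics(counts)
    if len(np.unique(y)) == 2:
        roc_points, auc = roc_and_auc(y, s)
    else:
        roc_points, auc = [], UNDEFINED
    return MetricsReport(counts=counts, roc_points=roc_points, auc=auc, **scalars)
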