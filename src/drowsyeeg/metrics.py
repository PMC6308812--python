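"""Confusion counts, the five derived classification metrics, and ROC/AUC.

The positive class throughout is *drowsy*: TP counts drowsy windows
classified drowsy, TN alert windows classified alert.  The five metrics

    precision   = TP / (TP + FP)
    sensitivity = TP / (TP + FN)            (recall)
    specificity = TN / (TN + FP)
    accuracy    = (TP + TN) / (TP + FP + FN + TN)
    F-measure   = 2 * precision * recall / (precision + recall)

are reported as percentages.  A metric whose denominator is zero is
*undefined* (NaN / JSON null), never silently 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from sklearn.metrics import roc_curve as _sk_roc_curve


@dataclass(frozen=True)
class ConfusionCounts:
    """TP/FP/FN/TN window counts for a binary alert/drowsy evaluation."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn", "tn"):
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise ValueError(f"{name} must be a non-negative integer, got {v}")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp,
            self.fp + other.fp,
            self.fn + other.fn,
            self.tn + other.tn,
        )


@dataclass
class MetricsReport:
    """The five metrics (percent) with their confusion counts and optional AUC."""

    counts: ConfusionCounts
    precision: float
    sensitivity: float
    specificity: float
    accuracy: float
    f_measure: float
    auc: float | None = None

    def to_dict(self) -> dict:
        def enc(v):
            if v is None or (isinstance(v, float) and math.isnan(v)):
                return None
            return round(float(v), 4)

        return {
            "counts": {
                "tp": self.counts.tp,
                "fp": self.counts.fp,
                "fn": self.counts.fn,
                "tn": self.counts.tn,
            },
            "precision": enc(self.precision),
            "sensitivity": enc(self.sensitivity),
            "specificity": enc(self.specificity),
            "accuracy": enc(self.accuracy),
            "f_measure": enc(self.f_measure),
            "auc": enc(self.auc),
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "MetricsReport":
        c = payload["counts"]

        def dec(v):
            return float("nan") if v is None else float(v)

        auc = payload.get("auc")
        return cls(
            counts=ConfusionCounts(c["tp"], c["fp"], c["fn"], c["tn"]),
            precision=dec(payload["precision"]),
            sensitivity=dec(payload["sensitivity"]),
            specificity=dec(payload["specificity"]),
            accuracy=dec(payload["accuracy"]),
            f_measure=dec(payload["f_measure"]),
            auc=None if auc is None else float(auc),
        )


def _ratio(num: float, den: float) -> float:
    return float("nan") if den == 0 else 100.0 * num / den


def compute_metrics(counts: ConfusionCounts, auc: float | None = None) -> MetricsReport:
    """Derive the five metrics (in percent) from confusion counts."""
    if counts.total == 0:
        raise ValueError("cannot compute metrics from zero evaluated windows")
    precision = _ratio(counts.tp, counts.tp + counts.fp)
    sensitivity = _ratio(counts.tp, counts.tp + counts.fn)
    specificity = _ratio(counts.tn, counts.tn + counts.fp)
    accuracy = _ratio(counts.tp + counts.tn, counts.total)
    if math.isnan(precision) or math.isnan(sensitivity) or precision + sensitivity == 0:
        f_measure = float("nan")
    else:
        f_measure = 2.0 * precision * sensitivity / (precision + sensitivity)
    return MetricsReport(
        counts=counts,
        precision=precision,
        sensitivity=sensitivity,
        specificity=specificity,
        accuracy=accuracy,
        f_measure=f_measure,
        auc=auc,
    )


def confusion_from_predictions(y_true, y_pred) -> ConfusionCounts:
    """Count TP/FP/FN/TN with 1 = drowsy (positive), 0 = alert."""
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    return ConfusionCounts(
        tp=int(np.sum((y_true == 1) & (y_pred == 1))),
        fp=int(np.sum((y_true == 0) & (y_pred == 1))),
        fn=int(np.sum((y_true == 1) & (y_pred == 0))),
        tn=int(np.sum((y_true == 0) & (y_pred == 0))),
    )


def roc_points(scores, labels):
    """ROC operating points (FPR, TPR, thresholds) over all score cutoffs.

    ``labels`` are binary with 1 = drowsy; higher scores mean more drowsy.
    """
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise ValueError("ROC requires both classes present")
    fpr, tpr, thr = _sk_roc_curve(labels, np.asarray(scores, dtype=float))
    return fpr, tpr, thr


def auc_trapezoid(fpr, tpr) -> float:
    """Area under the ROC polygon by the trapezoid rule over sorted FPR."""
    order = np.argsort(fpr, kind="stable")
    return float(np.trapezoid(np.asarray(tpr)[order], np.asarray(fpr)[order]))


def roc_auc(scores, labels) -> float:
    """Trapezoid AUC of the ROC curve (in [0, 1])."""
    fpr, tpr, _ = roc_points(scores, labels)
    return auc_trapezoid(fpr, tpr)
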