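"""Confusion-matrix metrics and ROC/AUC.

Sensitivity, specificity and accuracy are reported in percent:

    Sen = TP/(TP+FN) x 100,  Spe = TN/(TN+FP) x 100,
    Acc = (TP+TN)/(TP+FP+FN+TN) x 100

with class 1 as the positive class.  A degenerate denominator (no positive
or no negative truth) yields NaN as an explicit undefined marker rather
than an exception.  The ROC curve sweeps the unique score thresholds (tied
scores collapse into one step) and AUC is the trapezoid area, which equals
the probability that a random positive outscores a random negative with
ties counted one half.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve as _roc_curve

from .errors import DataValidationError

__all__ = ["MetricsReport", "confusion_metrics", "roc_curve_auc"]


@dataclass
class MetricsReport:
    """Classification performance of one evaluated gene subset."""

    tp: int | None = None
    fp: int | None = None
    tn: int | None = None
    fn: int | None = None
    sensitivity: float = float("nan")
    specificity: float = float("nan")
    accuracy: float = float("nan")
    auc: float | None = None
    roc_points: np.ndarray | None = None  # ordered (FPR, TPR) pairs
    roc_thresholds: np.ndarray | None = None

    def to_dict(self) -> dict:
        d = {
            "tp": self.tp,
            "fp": self.fp,
            "tn": self.tn,
            "fn": self.fn,
            "sensitivity_pct": self.sensitivity,
            "specificity_pct": self.specificity,
            "accuracy_pct": self.accuracy,
        }
        if self.auc is not None:
            d["auc"] = self.auc
        return d

    def summary(self) -> str:
        def fmt(x):
            return "-" if x is None or (isinstance(x, float) and np.isnan(x)) else f"{x:.2f}"

        lines = [
            f"Accuracy (%):    {fmt(self.accuracy)}",
            f"Sensitivity (%): {fmt(self.sensitivity)}",
            f"Specificity (%): {fmt(self.specificity)}",
        ]
        if self.auc is not None:
            lines.append(f"AUC:             {self.auc:.4f}")
        return "\n".join(lines)


def _check_binary(values, name: str) -> np.ndarray:
    arr = np.asarray(values)
    uniq = set(np.unique(arr).tolist())
    if not uniq <= {0, 1, 0.0, 1.0}:
        raise DataValidationError(f"{name} must take values in {{0, 1}}; found {sorted(uniq)}")
    return arr.astype(int)


def confusion_metrics(y_true, y_pred) -> MetricsReport:
    """Sensitivity/specificity/accuracy (percent) from binary predictions."""
    yt = _check_binary(y_true, "y_true")
    yp = _check_binary(y_pred, "y_pred")
    if yt.shape != yp.shape:
        raise DataValidationError(
            f"length mismatch: {yt.shape[0]} true labels, {yp.shape[0]} predictions"
        )
    tp = int(((yt == 1) & (yp == 1)).sum())
    fn = int(((yt == 1) & (yp == 0)).sum())
    tn = int(((yt == 0) & (yp == 0)).sum())
    fp = int(((yt == 0) & (yp == 1)).sum())
    sen = 100.0 * tp / (tp + fn) if tp + fn else float("nan")
    spe = 100.0 * tn / (tn + fp) if tn + fp else float("nan")
    acc = 100.0 * (tp + tn) / (tp + fp + fn + tn)
    return MetricsReport(tp=tp, fp=fp, tn=tn, fn=fn, sensitivity=sen, specificity=spe, accuracy=acc)


def roc_curve_auc(y_true, scores) -> MetricsReport:
    """ROC points and trapezoid AUC from continuous class-1 scores."""
    yt = _check_binary(y_true, "y_true")
    scores = np.asarray(scores, dtype=float)
    if yt.shape != scores.shape:
        raise DataValidationError(
            f"length mismatch: {yt.shape[0]} labels, {scores.shape[0]} scores"
        )
    if len(set(yt.tolist())) < 2:
        raise DataValidationError("ROC requires both classes in y_true")
    fpr, tpr, thresholds = _roc_curve(yt, scores, drop_intermediate=False)
    return MetricsReport(
        auc=float(_trapezoid_auc(fpr, tpr)),
        roc_points=np.column_stack([fpr, tpr]),
        roc_thresholds=thresholds,
    )
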