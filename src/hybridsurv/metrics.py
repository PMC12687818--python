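"""Classification evaluation: confusion matrix, per-class metrics, the
macro-F1 threshold sweep on [0.40, 0.70], and the Brier score.

Class 1 is "survived" throughout.  Undefined metrics (zero denominator) are
flagged and counted as 0 in macro averages, so a degenerate all-one-class
prediction still yields a usable macro-F1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ConfusionMatrix",
    "confusion",
    "MetricsReport",
    "class_metrics",
    "brier",
    "ThresholdCurve",
    "threshold_sweep",
    "THRESHOLD_GRID",
]

#: The 100 evenly spaced candidate decision thresholds.
THRESHOLD_GRID = np.linspace(0.40, 0.70, 100)


@dataclass(frozen=True)
class ConfusionMatrix:
    tn: int
    fp: int
    fn: int
    tp: int

    @property
    def total(self) -> int:
        return self.tn + self.fp + self.fn + self.tp

    def __post_init__(self) -> None:
        if min(self.tn, self.fp, self.fn, self.tp) < 0:
            raise ValueError("counts must be non-negative")


def confusion(y_true, y_pred) -> ConfusionMatrix:
    """Count tn/fp/fn/tp with class 1 = survived."""
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    tn = int(np.sum((y_true == 0) & (y_pred == 0)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    return ConfusionMatrix(tn, fp, fn, tp)


@dataclass
class MetricsReport:
    accuracy: float
    precision: dict
    recall: dict
    f1: dict
    specificity: float
    macro_f1: float
    undefined: list = field(default_factory=list)
    brier: float | None = None
    threshold: float | None = None


def _safe_div(num: float, den: float, name: str, undefined: list) -> float:
    if den == 0:
        undefined.append(name)
        return 0.0
    return num / den


def class_metrics(cm: ConfusionMatrix) -> MetricsReport:
    """Accuracy, per-class precision/recall/F1, specificity and macro-F1.

    For class 1: precision = tp/(tp+fp), recall = tp/(tp+fn); class 0
    mirrors with tn.  Specificity is class-0 recall.  F1 is the harmonic
    mean; macro-F1 the unweighted mean of the two class F1 values.
    """
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    undefined: list = []
    acc = (cm.tn + cm.tp) / cm.total
    prec1 = _safe_div(cm.tp, cm.tp + cm.fp, "precision_1", undefined)
    rec1 = _safe_div(cm.tp, cm.tp + cm.fn, "recall_1", undefined)
    prec0 = _safe_div(cm.tn, cm.tn + cm.fn, "precision_0", undefined)
    rec0 = _safe_div(cm.tn, cm.tn + cm.fp, "recall_0", undefined)
    f1_1 = _safe_div(2 * prec1 * rec1, prec1 + rec1, "f1_1", undefined)
    f1_0 = _safe_div(2 * prec0 * rec0, prec0 + rec0, "f1_0", undefined)
    return MetricsReport(
        accuracy=acc,
        precision={0: prec0, 1: prec1},
        recall={0: rec0, 1: rec1},
        f1={0: f1_0, 1: f1_1},
        specificity=rec0,
        macro_f1=(f1_0 + f1_1) / 2.0,
        undefined=undefined,
    )


def brier(probs, y_true) -> float:
    """Mean squared difference between predicted survival probabilities and
    binary outcomes; 0 is perfect, 0.25 is the constant-0.5 predictor."""
    probs = np.asarray(probs, dtype=float)
    y_true = np.asarray(y_true, dtype=float)
    if probs.shape != y_true.shape:
        raise ValueError("probs and y_true must have equal length")
    if np.any((probs < 0) | (probs > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    return float(np.mean((probs - y_true) ** 2))


@dataclass
class ThresholdCurve:
    grid: np.ndarray
    macro_f1: np.ndarray
    optimal: float

    @property
    def optimal_index(self) -> int:
        return int(np.flatnonzero(np.isclose(self.grid, self.optimal))[0])


def threshold_sweep(probs, y_true) -> ThresholdCurve:
    """Macro-F1 across the 100-point threshold grid; prediction rule is
    prob >= tau (inclusive); ties broken toward the smallest threshold."""
    probs = np.asarray(probs, dtype=float)
    y_true = np.asarray(y_true, dtype=int)
    if len(np.unique(y_true)) < 2:
        raise ValueError("both classes must be present to sweep thresholds")
    scores = np.empty(len(THRESHOLD_GRID))
    for i, tau in enumerate(THRESHOLD_GRID):
        scores[i] = class_metrics(confusion(y_true, (probs >= tau).astype(int))).macro_f1
    best = int(np.argmax(scores))  # argmax returns the first (smallest tau)
    return ThresholdCurve(grid=THRESHOLD_GRID.copy(), macro_f1=scores, optimal=float(THRESHOLD_GRID[best]))
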