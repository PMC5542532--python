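"""Confusion-matrix metrics for imbalanced two-class evaluation.

Accuracy alone is misleading under class imbalance (predicting the
majority everywhere can score high), so the geometric mean of sensitivity
and specificity (G-mean) and the F-measure are reported alongside it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = ["ConfusionCounts", "confusion", "accuracy", "g_mean", "f_measure"]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fn: int
    fp: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.fp + self.tn


def confusion(y_true, y_pred, positive) -> ConfusionCounts:
    """Tally a 2x2 confusion matrix, minority class = positive.

    Every label in either sequence must belong to the two labels present
    in ``y_true`` (with ``positive`` one of them).
    """
    yt = np.asarray(y_true).ravel()
    yp = np.asarray(y_pred).ravel()
    if yt.size != yp.size:
        raise ValueError("y_true and y_pred must have equal length")
    labels = set(np.unique(yt).tolist()) | {positive}
    if len(labels) > 2:
        raise ValueError(f"labels are not binary: {sorted(map(str, labels))}")
    foreign = set(np.unique(yp).tolist()) - labels
    if foreign:
        raise ValueError(f"foreign label(s) in predictions: {sorted(map(str, foreign))}")
    tpos = yt == positive
    ppos = yp == positive
    return ConfusionCounts(
        tp=int(np.sum(tpos & ppos)),
        fn=int(np.sum(tpos & ~ppos)),
        fp=int(np.sum(~tpos & ppos)),
        tn=int(np.sum(~tpos & ~ppos)),
    )


def _check(c: ConfusionCounts) -> None:
    if min(c.tp, c.fn, c.fp, c.tn) < 0:
        raise ValueError("negative count")
    if c.total == 0:
        raise ValueError("all counts are zero")


def _ratio(num: int, den: int) -> float:
    # 0/0 convention: an empty denominator yields rate 0
    return num / den if den else 0.0


def accuracy(c: ConfusionCounts) -> float:
    _check(c)
    return (c.tp + c.tn) / c.total


def g_mean(c: ConfusionCounts) -> float:
    """sqrt(TPR * TNR): zero as soon as either class is entirely missed."""
    _check(c)
    tpr = _ratio(c.tp, c.tp + c.fn)
    tnr = _ratio(c.tn, c.tn + c.fp)
    return math.sqrt(tpr * tnr)


def f_measure(c: ConfusionCounts) -> float:
    """Harmonic mean of precision and recall on the positive class."""
    _check(c)
    p = _ratio(c.tp, c.tp + c.fp)
    r = _ratio(c.tp, c.tp + c.fn)
    return _ratio_f(p, r)


def _ratio_f(p: float, r: float) -> float:
    return 2.0 * p * r / (p + r) if p + r else 0.0
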