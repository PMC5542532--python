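"""Box-and-whisker statistics and Tukey inner-fence outlier screening.

One-dimensional screening rule: a value is a *suspected outlier* when it
falls outside [LIF, UIF] where LIF = Q1 - 1.5*IQR and UIF = Q3 + 1.5*IQR.
Quartiles default to Tukey hinges (medians of the lower/upper halves,
halves including the overall median for odd n), the convention of the
original box plot; a linear-interpolation alternative is available.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["BoxStats", "compute_box_stats", "flag_outliers"]

#: fence multiplier for the *inner* fences
FENCE_FACTOR = 1.5


@dataclass(frozen=True)
class BoxStats:
    """Quartiles, interquartile range and inner fences of one feature."""

    q1: float
    q2: float
    q3: float
    iqr: float
    lif: float
    uif: float


def _check(values) -> np.ndarray:
    x = np.asarray(values, dtype=float)
    if x.ndim != 1:
        x = x.ravel()
    if x.size == 0:
        raise ValueError("empty feature")
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite input")
    return x


def _tukey_hinges(x_sorted: np.ndarray) -> tuple[float, float]:
    n = x_sorted.size
    # odd n: both halves include the median; even n: clean split
    lower = x_sorted[: (n + 1) // 2]
    upper = x_sorted[n // 2 :]
    return float(np.median(lower)), float(np.median(upper))


def compute_box_stats(values, convention: str = "hinges") -> BoxStats:
    """Quartiles, IQR and inner fences of ``values``.

    Parameters
    ----------
    values : array-like of finite reals, length >= 1
    convention : {"hinges", "linear"}
        "hinges" uses Tukey hinges; "linear" uses the linear-interpolation
        percentile definition (numpy default).
    """
    x = np.sort(_check(values))
    q2 = float(np.median(x))
    if convention == "hinges":
        q1, q3 = _tukey_hinges(x)
    elif convention == "linear":
        q1 = float(np.percentile(x, 25))
        q3 = float(np.percentile(x, 75))
    else:
        raise ValueError(f"unknown quartile convention: {convention!r}")
    iqr = q3 - q1
    return BoxStats(
        q1=q1,
        q2=q2,
        q3=q3,
        iqr=iqr,
        lif=q1 - FENCE_FACTOR * iqr,
        uif=q3 + FENCE_FACTOR * iqr,
    )


def flag_outliers(values, convention: str = "hinges") -> np.ndarray:
    """Boolean mask, True where a value lies outside the inner fences."""
    x = _check(values)
    stats = compute_box_stats(x, convention=convention)
    return (x < stats.lif) | (x > stats.uif)
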