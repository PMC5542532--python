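"""Mega-trend-diffusion (MTD) domain estimation and alpha-cut filtering.

MTD estimates a plausible domain [a, b] around a small sample by diffusing
outward from u_set = (min + max) / 2, scaled by the sample variance and
weighted by the skewness of the sample about u_set:

    a = u_set - S_L * sqrt(-2 * s^2 / N_L * ln(1e-20))
    b = u_set + S_U * sqrt(-2 * s^2 / N_U * ln(1e-20))

where N_L / N_U count observations strictly below / above u_set and
S_L = N_L / (N_L + N_U), S_U = N_U / (N_L + N_U).  A triangular fuzzy
membership peaks at u_set (value 1) and falls to 0 at a and b; the
alpha-cut A_alpha is the sub-interval where membership >= alpha, used here
to retain only the "representative" core of a majority class.

Constant (zero-variance) samples have N_L = N_U = 0; the bounds then fall
back to a = min/5 and b = 5*max and the model is flagged degenerate.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "DIFFUSION_LOG",
    "MTDModel",
    "AlphaCutInterval",
    "fit_mtd",
    "membership",
    "alpha_cut_region",
    "filter_by_alpha_cut",
]

#: diffusion constant ln(10^-20) used in the domain-range formulas
DIFFUSION_LOG = -20.0 * math.log(10.0)


@dataclass(frozen=True)
class MTDModel:
    """MTD domain estimate for one feature."""

    u_set: float
    data_min: float
    data_max: float
    n_l: int
    n_u: int
    s_l: float
    s_u: float
    variance: float
    a: float
    b: float
    diffusion_log: float = DIFFUSION_LOG

    @property
    def degenerate(self) -> bool:
        """True for zero-spread samples, where the triangle collapses."""
        return self.variance == 0.0


@dataclass(frozen=True)
class AlphaCutInterval:
    lo: float
    hi: float
    alpha: float


def fit_mtd(values) -> MTDModel:
    """Estimate the MTD domain range of a univariate sample."""
    x = np.asarray(values, dtype=float).ravel()
    if x.size == 0:
        raise ValueError("empty feature")
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite input")
    mn, mx = float(x.min()), float(x.max())
    u_set = (mn + mx) / 2.0
    n_l = int(np.sum(x < u_set))
    n_u = int(np.sum(x > u_set))
    variance = float(np.var(x, ddof=1)) if x.size > 1 else 0.0
    total = n_l + n_u
    s_l = n_l / total if total > 0 else 0.5
    s_u = n_u / total if total > 0 else 0.5

    if n_l == 0:
        a = mn / 5.0
    else:
        a = u_set - s_l * math.sqrt(-2.0 * variance / n_l * DIFFUSION_LOG)
    if n_u == 0:
        b = mx * 5.0
    else:
        b = u_set + s_u * math.sqrt(-2.0 * variance / n_u * DIFFUSION_LOG)

    if n_l > 0 and a > mn:
        warnings.warn(
            "MTD lower bound exceeds the sample minimum; observed values "
            "below it get membership 0 and are filtered at any alpha",
            stacklevel=2,
        )
    if n_u > 0 and b < mx:
        warnings.warn(
            "MTD upper bound is below the sample maximum; observed values "
            "above it get membership 0 and are filtered at any alpha",
            stacklevel=2,
        )
    return MTDModel(
        u_set=u_set,
        data_min=mn,
        data_max=mx,
        n_l=n_l,
        n_u=n_u,
        s_l=s_l,
        s_u=s_u,
        variance=variance,
        a=a,
        b=b,
    )


def membership(model: MTDModel, x) -> np.ndarray | float:
    """Triangular membership in [0, 1]; peak 1 at u_set, 0 at/outside a, b."""
    xv = np.asarray(x, dtype=float)
    if model.degenerate:
        out = np.where(xv == model.u_set, 1.0, 0.0)
        return float(out) if out.ndim == 0 else out
    a, b, u = model.a, model.b, model.u_set
    left = (xv - a) / (u - a) if u > a else (xv == u).astype(float)
    right = (b - xv) / (b - u) if b > u else (xv == u).astype(float)
    out = np.where(xv <= u, left, right)
    out = np.clip(out, 0.0, 1.0)
    return float(out) if out.ndim == 0 else out


def alpha_cut_region(model: MTDModel, alpha: float) -> AlphaCutInterval:
    """Crisp interval where membership >= alpha:
    [ (u_set - a)*alpha + a,  b - (b - u_set)*alpha ]."""
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")
    if model.degenerate and not (model.a <= model.u_set <= model.b):
        raise ValueError("degenerate MTD model has an inverted domain")
    lo = (model.u_set - model.a) * alpha + model.a
    hi = model.b - (model.b - model.u_set) * alpha
    return AlphaCutInterval(lo=lo, hi=hi, alpha=alpha)


def filter_by_alpha_cut(values, model: MTDModel, alpha: float) -> np.ndarray:
    """Boolean retain-mask: True where lo <= value <= hi (closed interval)."""
    region = alpha_cut_region(model, alpha)
    x = np.asarray(values, dtype=float)
    return (x >= region.lo) & (x <= region.hi)
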