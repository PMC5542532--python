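"""ppdp: distribution-aware resampling for imbalanced two-class tables.

Undersamples the majority class by Tukey-fence outlier deletion followed
by mega-trend-diffusion alpha-cut filtering, and oversamples the minority
class from per-feature two-parameter Weibull fits (shape by a
maximal-p-value Gini spacings test, scale in closed form, samples by
median-rank inversion), yielding a balanced training table.
"""

from . import boxwhisker, fixtures, metrics, mtd, resampler, weibull
from .boxwhisker import BoxStats, compute_box_stats, flag_outliers
from .metrics import ConfusionCounts, accuracy, confusion, f_measure, g_mean
from .mtd import MTDModel, alpha_cut_region, filter_by_alpha_cut, fit_mtd, membership
from .resampler import (
    PPDP,
    LabeledDataset,
    PPDPResults,
    ResampleConfig,
    ResampleReport,
    ppdp_resample,
    read_table,
    write_report,
    write_table,
)
from .weibull import BetaGrid, WeibullFit, fit_weibull, generate_samples

__version__ = "0.1.0"

__all__ = [
    "BoxStats", "compute_box_stats", "flag_outliers",
    "MTDModel", "fit_mtd", "membership", "alpha_cut_region", "filter_by_alpha_cut",
    "BetaGrid", "WeibullFit", "fit_weibull", "generate_samples",
    "ConfusionCounts", "confusion", "accuracy", "g_mean", "f_measure",
    "LabeledDataset", "ResampleConfig", "ResampleReport", "ppdp_resample",
    "read_table", "write_table", "write_report",
    "PPDP", "PPDPResults",
    "boxwhisker", "mtd", "weibull", "resampler", "metrics", "fixtures",
]
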