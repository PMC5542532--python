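"""The full pre-processing pipeline for imbalanced two-class tables.

Four steps:

1. split the training table by class (majority size M, minority size m);
2. undersample the majority: delete rows flagged by the box-whisker fence
   rule in any feature (S_box rows), then refit the mega-trend-diffusion
   domain per feature on the survivors and delete rows outside the
   alpha-cut in any feature (S_mtd rows), leaving M' = M - S_box - S_mtd;
3. oversample the minority: fit a two-parameter Weibull to each feature
   and append M' - m synthetic rows by median-rank inversion;
4. merge into a balanced table of M' rows per class.

The statsmodels-style surface is :class:`PPDP` (model) whose ``fit()``
returns :class:`PPDPResults` (balanced data, per-feature sub-models,
counts, ``summary()``).  The functional core ``ppdp_resample`` and the
stage functions are public too.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import boxwhisker, mtd, weibull

__all__ = [
    "LabeledDataset",
    "ResampleConfig",
    "ResampleReport",
    "split_by_class",
    "undersample_majority",
    "oversample_minority",
    "ppdp_resample",
    "read_table",
    "write_table",
    "write_report",
    "PPDP",
    "PPDPResults",
]


@dataclass
class LabeledDataset:
    """An N x P numeric feature matrix with one label per row."""

    features: np.ndarray
    labels: np.ndarray
    feature_names: list[str]
    positive_label: object = None

    def __post_init__(self):
        self.features = np.asarray(self.features, dtype=float)
        if self.features.ndim == 1:
            self.features = self.features.reshape(-1, 1)
        self.labels = np.asarray(self.labels)
        if self.features.shape[0] != self.labels.shape[0]:
            raise ValueError("row count of features must equal label count")
        if len(self.feature_names) != self.features.shape[1]:
            raise ValueError("feature_names length must equal feature count")

    @property
    def n_rows(self) -> int:
        return self.features.shape[0]

    @property
    def n_features(self) -> int:
        return self.features.shape[1]

    def class_counts(self) -> dict:
        vals, counts = np.unique(self.labels, return_counts=True)
        return dict(zip(vals.tolist(), counts.tolist()))

    def take(self, idx) -> "LabeledDataset":
        idx = np.asarray(idx)
        return LabeledDataset(
            self.features[idx], self.labels[idx], list(self.feature_names), self.positive_label
        )

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, label_column: str, positive_label=None
    ) -> "LabeledDataset":
        if label_column not in df.columns:
            raise ValueError(f"label column {label_column!r} not found")
        feat = df.drop(columns=[label_column])
        for col in feat.columns:
            if not pd.api.types.is_numeric_dtype(feat[col]):
                bad = feat[col][pd.to_numeric(feat[col], errors="coerce").isna()]
                row = bad.index[0] if len(bad) else "?"
                raise ValueError(f"non-numeric feature cell at row {row}, column {col!r}")
        if feat.isna().any().any():
            col = feat.columns[feat.isna().any()][0]
            row = feat.index[feat[col].isna()][0]
            raise ValueError(f"missing value at row {row}, column {col!r}")
        return cls(
            features=feat.to_numpy(dtype=float),
            labels=df[label_column].to_numpy(),
            feature_names=list(feat.columns),
            positive_label=positive_label,
        )

    def to_dataframe(self, label_column: str = "class") -> pd.DataFrame:
        df = pd.DataFrame(self.features, columns=self.feature_names)
        df[label_column] = self.labels
        return df


@dataclass(frozen=True)
class ResampleConfig:
    """Tuning knobs of the pipeline; ``alpha`` is the membership cut-off."""

    alpha: float = 0.5
    seed: int = 0
    outlier_rule: str = "any_feature"
    generation_mode: str = "permuted"  # or "median_rank"
    beta_grid: weibull.BetaGrid = field(default_factory=weibull.BetaGrid)
    quartile_convention: str = "hinges"

    def __post_init__(self):
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")
        if self.outlier_rule != "any_feature":
            raise ValueError("only the any_feature outlier rule is supported")
        if self.generation_mode not in ("permuted", "median_rank"):
            raise ValueError(f"unknown generation mode: {self.generation_mode!r}")


@dataclass
class ResampleReport:
    """Counts and per-feature sub-models of one pipeline run."""

    m_major: int
    s_box: int
    s_mtd: int
    m_major_prime: int
    m_minor: int
    m_minor_prime: int
    n_synthetic: int
    per_feature: dict
    removed_row_ids: dict  # {"box": [...], "mtd": [...]} indices into the majority block
    seed: int = 0

    def to_dict(self) -> dict:
        def conv(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: conv(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, dict):
                return {str(k): conv(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple, np.ndarray)):
                return [conv(v) for v in obj]
            if isinstance(obj, (np.integer,)):
                return int(obj)
            if isinstance(obj, (np.floating,)):
                return float(obj)
            return obj

        return conv(dataclasses.asdict(self))


def split_by_class(dataset: LabeledDataset) -> tuple[LabeledDataset, LabeledDataset]:
    """(minority, majority); the minority is the smaller class, ties going
    to the declared positive label."""
    counts = dataset.class_counts()
    if len(counts) != 2:
        raise ValueError(f"expected exactly two classes, found {len(counts)}")
    (l1, c1), (l2, c2) = counts.items()
    if c1 == c2:
        if dataset.positive_label is None:
            raise ValueError("equal class sizes and no positive_label declared")
        warnings.warn("equal class sizes; taking the declared positive label as minority")
        pos = dataset.positive_label
    elif dataset.positive_label is not None:
        pos = dataset.positive_label
        if pos not in counts:
            raise ValueError(f"positive label {pos!r} not present in the data")
        if counts[pos] != min(c1, c2):
            warnings.warn("declared positive label is not the smaller class")
            pos = l1 if c1 < c2 else l2
    else:
        pos = l1 if c1 < c2 else l2
    pos_mask = dataset.labels == pos
    minority = dataset.take(np.flatnonzero(pos_mask))
    majority = dataset.take(np.flatnonzero(~pos_mask))
    minority.positive_label = majority.positive_label = pos
    return minority, majority


def undersample_majority(
    majority: LabeledDataset, config: ResampleConfig | None = None
) -> tuple[LabeledDataset, int, int, dict, dict]:
    """Two-stage deletion; returns (reduced, s_box, s_mtd, models, removed_ids).

    Stage 1 removes any row outside the inner fences in at least one
    feature.  Stage 2 refits the MTD domain per feature on the survivors
    and removes any row outside that feature's alpha-cut; zero-variance
    features are skipped in stage 2.
    """
    if majority.n_rows == 0:
        raise ValueError("majority class is empty")
    config = config or ResampleConfig()
    X = majority.features
    models: dict[str, dict] = {name: {} for name in majority.feature_names}

    out_mask = np.zeros(majority.n_rows, dtype=bool)
    for j, name in enumerate(majority.feature_names):
        models[name]["box"] = boxwhisker.compute_box_stats(
            X[:, j], convention=config.quartile_convention
        )
        out_mask |= boxwhisker.flag_outliers(X[:, j], convention=config.quartile_convention)
    box_ids = np.flatnonzero(out_mask)
    survivors = np.flatnonzero(~out_mask)
    if survivors.size == 0:
        raise ValueError("box-whisker stage removed the entire majority class")

    Xs = X[survivors]
    drop_mask = np.zeros(survivors.size, dtype=bool)
    for j, name in enumerate(majority.feature_names):
        model = mtd.fit_mtd(Xs[:, j])
        models[name]["mtd"] = model
        if model.degenerate:
            continue  # a collapsed triangle would retain only exact ties
        keep = mtd.filter_by_alpha_cut(Xs[:, j], model, config.alpha)
        drop_mask |= ~keep
    mtd_ids = survivors[drop_mask]
    kept = survivors[~drop_mask]
    if kept.size == 0:
        raise ValueError("alpha-cut removed entire majority class; lower alpha")

    removed = {"box": box_ids.tolist(), "mtd": mtd_ids.tolist()}
    return majority.take(kept), int(box_ids.size), int(mtd_ids.size), models, removed


def oversample_minority(
    minority: LabeledDataset,
    n_synthetic: int,
    config: ResampleConfig | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[LabeledDataset, dict]:
    """Append ``n_synthetic`` Weibull median-rank rows; returns (extended, fits).

    Every minority feature is fitted independently on ALL minority rows
    (no outlier removal on the minority side).  In ``permuted`` mode each
    synthetic column is independently shuffled so features are not
    comonotone across the synthetic block.
    """
    if minority.n_rows < 3:
        raise ValueError("minority class size must be at least three")
    if n_synthetic < 0:
        raise ValueError("n_synthetic must be nonnegative")
    config = config or ResampleConfig()
    rng = rng or np.random.default_rng(config.seed)
    fits = {
        name: weibull.fit_weibull(minority.features[:, j], config.beta_grid)
        for j, name in enumerate(minority.feature_names)
    }
    if n_synthetic == 0:
        return minority, fits
    cols = [
        weibull.generate_samples(fits[name], n_synthetic, mode=config.generation_mode, rng=rng)
        for name in minority.feature_names
    ]
    synth = np.column_stack(cols)
    pos = minority.positive_label
    if pos is None:
        pos = minority.labels[0]
    extended = LabeledDataset(
        np.vstack([minority.features, synth]),
        np.concatenate([minority.labels, np.full(n_synthetic, pos, dtype=minority.labels.dtype)]),
        list(minority.feature_names),
        minority.positive_label,
    )
    return extended, fits


def ppdp_resample(
    dataset: LabeledDataset, config: ResampleConfig | None = None
) -> tuple[LabeledDataset, ResampleReport]:
    """Run the full pipeline; deterministic given ``config.seed``."""
    config = config or ResampleConfig()
    minority, majority = split_by_class(dataset)
    m_major, m_minor = majority.n_rows, minority.n_rows

    reduced, s_box, s_mtd, models, removed = undersample_majority(majority, config)
    m_prime = reduced.n_rows
    n_synth = max(m_prime - m_minor, 0)
    if m_prime <= m_minor:
        warnings.warn("classes already balanced after undersampling")

    rng = np.random.default_rng(config.seed)
    extended, fits = oversample_minority(minority, n_synth, config, rng)
    for name, f in fits.items():
        models[name]["weibull"] = f

    balanced = LabeledDataset(
        np.vstack([reduced.features, extended.features]),
        np.concatenate([reduced.labels, extended.labels]),
        list(dataset.feature_names),
        minority.positive_label,
    )
    report = ResampleReport(
        m_major=m_major,
        s_box=s_box,
        s_mtd=s_mtd,
        m_major_prime=m_prime,
        m_minor=m_minor,
        m_minor_prime=extended.n_rows,
        n_synthetic=n_synth,
        per_feature=models,
        removed_row_ids=removed,
        seed=config.seed,
    )
    return balanced, report


# ---------------------------------------------------------------------------
# tabular I/O

def read_table(path, label_column: str, positive_label=None) -> LabeledDataset:
    """Load a CSV with a header row into a LabeledDataset (two classes)."""
    df = pd.read_csv(path, float_precision="round_trip")
    ds = LabeledDataset.from_dataframe(df, label_column, positive_label)
    n_classes = len(ds.class_counts())
    if n_classes != 2:
        raise ValueError(f"expected exactly two classes in {label_column!r}, found {n_classes}")
    return ds


def write_table(dataset: LabeledDataset, path, label_column: str = "class") -> None:
    # 17 significant digits: lossless float64 round trip
    dataset.to_dataframe(label_column).to_csv(path, index=False, float_format="%.17g")


def write_report(report: ResampleReport, path) -> None:
    with open(path, "w") as fh:
        json.dump(report.to_dict(), fh, indent=2)


# ---------------------------------------------------------------------------
# model / results surface

class PPDP:
    """Resampling model for one imbalanced two-class table.

    Parameters
    ----------
    features, labels : the training table (N x P numerics, N labels)
    feature_names : optional column names
    positive_label : label of the minority class of interest

    ``fit(alpha=..., seed=...)`` runs the pipeline and returns a
    :class:`PPDPResults`.
    """

    def __init__(self, features, labels, feature_names=None, positive_label=None):
        features = np.asarray(features, dtype=float)
        if features.ndim == 1:
            features = features.reshape(-1, 1)
        if feature_names is None:
            feature_names = [f"x{j}" for j in range(features.shape[1])]
        self.data = LabeledDataset(features, np.asarray(labels), list(feature_names), positive_label)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, label_column: str, positive_label=None) -> "PPDP":
        ds = LabeledDataset.from_dataframe(df, label_column, positive_label)
        obj = cls.__new__(cls)
        obj.data = ds
        return obj

    def fit(self, alpha: float = 0.5, seed: int = 0, **kwargs) -> "PPDPResults":
        config = ResampleConfig(alpha=alpha, seed=seed, **kwargs)
        balanced, report = ppdp_resample(self.data, config)
        return PPDPResults(self, config, balanced, report)


class PPDPResults:
    """Outcome of a pipeline run: balanced data, counts, per-feature fits."""

    def __init__(self, model: PPDP, config: ResampleConfig, balanced, report):
        self.model = model
        self.config = config
        self.balanced = balanced
        self.report = report

    def to_dataframe(self, label_column: str = "class") -> pd.DataFrame:
        return self.balanced.to_dataframe(label_column)

    def weibull_params(self) -> pd.DataFrame:
        rows = []
        for name, sub in self.report.per_feature.items():
            f = sub.get("weibull")
            if f is not None:
                rows.append(
                    {"feature": name, "beta": f.beta, "lamda": f.lamda,
                     "shift": f.shift, "p_value": f.p_value, "sse": f.sse}
                )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        r = self.report
        lines = [
            "PPDP resampling results",
            "=" * 55,
            f"alpha-cut: {self.config.alpha:<8} seed: {self.config.seed}",
            f"majority M:             {r.m_major}",
            f"  removed by fences:    {r.s_box}",
            f"  removed by alpha-cut: {r.s_mtd}",
            f"  retained M':          {r.m_major_prime}",
            f"minority m:             {r.m_minor}",
            f"  synthetic added:      {r.n_synthetic}",
            f"  extended m':          {r.m_minor_prime}",
            "-" * 55,
            "minority Weibull fits (per feature):",
        ]
        wp = self.weibull_params()
        if len(wp):
            lines.append(wp.to_string(index=False, float_format=lambda v: f"{v:.4f}"))
        else:
            lines.append("  (none fitted)")
        return "\n".join(lines)
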