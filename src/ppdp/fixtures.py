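"""Synthetic imbalanced datasets and the scenario/experiment harness.

The generator stands in for the small biomedical tables the pipeline is
aimed at: a majority class whose features share a latent severity factor
(clinical panels are near-collinear: correlated morphometric or
biochemical readouts of one underlying trait) with a controllable
fraction of rows given one far-outlying feature value, and a minority
class whose features are genuine two-parameter Weibull draws, so the
oversampler's parameter recovery is directly testable.  Feature
correlation matters here: the undersampler deletes a row when ANY feature
violates its alpha-cut, so independent features would compound the
per-feature removal rates multiplicatively, which real tables do not do.

Scenarios follow the r x N design: a training set of N rows containing
m = max(round(r% * N), 3) minority rows (round half up; the floor of three
is the smallest sample the Gini-test fit accepts), M = N - m majority
rows, the remainder of the source data serving as the test set.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import clone

from . import metrics
from .resampler import LabeledDataset, ResampleConfig, ppdp_resample

__all__ = [
    "FeatureSpec",
    "WeibullSpec",
    "FixtureSpec",
    "ScenarioSpec",
    "make_synthetic_imbalanced",
    "make_scenario",
    "minority_train_size",
    "run_experiment",
]


@dataclass(frozen=True)
class FeatureSpec:
    """Majority-class feature distribution (family in {normal, lognormal, uniform})."""

    location: float = 0.0
    scale: float = 1.0
    family: str = "normal"


@dataclass(frozen=True)
class WeibullSpec:
    """Minority-class feature distribution Weibull(beta, lamda) + shift."""

    beta: float = 2.0
    lamda: float = 1.0
    shift: float = 0.0


def _default_majority() -> tuple:
    return (
        FeatureSpec(10.0, 2.0),
        FeatureSpec(20.0, 4.0),
        FeatureSpec(5.0, 1.0),
        FeatureSpec(50.0, 8.0),
    )


def _default_minority() -> tuple:
    # partial overlap with the majority: shifted low relative to each
    # majority mean, Weibull shapes spanning skewed to mound-shaped
    return (
        WeibullSpec(1.5, 2.0, 4.0),
        WeibullSpec(2.0, 4.0, 10.0),
        WeibullSpec(2.5, 1.5, 1.5),
        WeibullSpec(1.8, 6.0, 30.0),
    )


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for one synthetic imbalanced dataset."""

    n_major: int = 400
    n_minor: int = 40
    majority_model: tuple = field(default_factory=_default_majority)
    minority_model: tuple = field(default_factory=_default_minority)
    rho: float = 0.95  # latent-factor correlation across majority features
    outlier_rate: float = 0.05
    seed: int = 0

    @property
    def p(self) -> int:
        return len(self.majority_model)

    def __post_init__(self):
        if self.n_minor < 3:
            raise ValueError("n_minor must be at least three")
        if len(self.majority_model) != len(self.minority_model):
            raise ValueError("majority and minority models must have equal feature counts")
        if not 0.0 <= self.outlier_rate < 1.0:
            raise ValueError("outlier_rate must lie in [0, 1)")
        if not 0.0 <= self.rho < 1.0:
            raise ValueError("rho must lie in [0, 1)")


@dataclass(frozen=True)
class ScenarioSpec:
    """One r x N cell of the experiment design."""

    r: float  # percentage of minority rows in the training set
    n_train: int
    repetitions: int = 50
    seed: int = 0


def _shape_majority(spec: FeatureSpec, latent: np.ndarray) -> np.ndarray:
    """Map a standard-normal latent column through the feature's family."""
    if spec.family == "normal":
        return spec.location + spec.scale * latent
    if spec.family == "lognormal":
        return spec.location + spec.scale * np.exp(latent)
    if spec.family == "uniform":
        from scipy.stats import norm

        return spec.location + spec.scale * (2.0 * norm.cdf(latent) - 1.0)
    raise ValueError(f"unknown majority family: {spec.family!r}")


def make_synthetic_imbalanced(spec: FixtureSpec) -> LabeledDataset:
    """Deterministic synthetic dataset; labels 1 = minority, 0 = majority."""
    rng = np.random.default_rng(spec.seed)
    # one latent severity factor shared across majority features
    z = rng.standard_normal((spec.n_major, 1))
    eps = rng.standard_normal((spec.n_major, spec.p))
    latent = math.sqrt(spec.rho) * z + math.sqrt(1.0 - spec.rho) * eps
    maj = np.column_stack(
        [_shape_majority(f, latent[:, j]) for j, f in enumerate(spec.majority_model)]
    )
    mino = np.column_stack(
        [w.shift + w.lamda * rng.weibull(w.beta, spec.n_minor) for w in spec.minority_model]
    )
    n_out = int(math.floor(spec.outlier_rate * spec.n_major))
    if n_out:
        rows = rng.choice(spec.n_major, n_out, replace=False)
        cols = rng.integers(0, spec.p, n_out)
        for i, j in zip(rows, cols):
            col = maj[:, j]
            q1, q3 = np.percentile(col, [25, 75])
            iqr = max(q3 - q1, 1e-9)
            sign = 1.0 if rng.random() < 0.5 else -1.0
            base = col.max() if sign > 0 else col.min()
            # displace well beyond 10 IQR so any fence convention flags it
            maj[i, j] = base + sign * (10.0 * iqr + rng.uniform(0.0, 2.0 * iqr))
    features = np.vstack([maj, mino])
    labels = np.concatenate([np.zeros(spec.n_major, int), np.ones(spec.n_minor, int)])
    names = [f"x{j}" for j in range(spec.p)]
    return LabeledDataset(features, labels, names, positive_label=1)


def minority_train_size(r: float, n_train: int) -> int:
    """m = round-half-up(r% * N), floored at three."""
    return max(int(math.floor(r / 100.0 * n_train + 0.5)), 3)


def make_scenario(
    dataset: LabeledDataset, spec: ScenarioSpec, rep: int
) -> tuple[LabeledDataset, LabeledDataset]:
    """Draw one (train, test) split; deterministic given (spec.seed, rep)."""
    m = minority_train_size(spec.r, spec.n_train)
    big = spec.n_train - m
    pos = dataset.positive_label
    pos_idx = np.flatnonzero(dataset.labels == pos)
    neg_idx = np.flatnonzero(dataset.labels != pos)
    if pos_idx.size < m or neg_idx.size < big:
        raise ValueError(
            f"dataset too small for scenario r={spec.r}, N={spec.n_train}: "
            f"needs {m} minority and {big} majority rows"
        )
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, rep]))
    tr_pos = rng.choice(pos_idx, m, replace=False)
    tr_neg = rng.choice(neg_idx, big, replace=False)
    train_ids = np.concatenate([tr_neg, tr_pos])
    test_ids = np.setdiff1d(np.arange(dataset.n_rows), train_ids)
    return dataset.take(train_ids), dataset.take(test_ids)


def _fit_predict(classifier, train: LabeledDataset, test: LabeledDataset) -> np.ndarray:
    est = clone(classifier) if hasattr(classifier, "get_params") else classifier()
    est.fit(train.features, train.labels)
    return est.predict(test.features)


def run_experiment(
    dataset: LabeledDataset,
    scenarios: list[ScenarioSpec],
    config: ResampleConfig | None = None,
    classifier=None,
) -> pd.DataFrame:
    """Mean ACC / G-mean / F1 over repetitions, raw vs resampled training.

    ``classifier`` is any sklearn-style estimator (fit/predict); it is
    cloned per run.  Returns a tidy table with one row per (scenario,
    training-variant).
    """
    if classifier is None:
        from sklearn.svm import SVC

        classifier = SVC(kernel="poly", degree=2, C=1.0)  # reference configuration
    config = config or ResampleConfig()
    pos = dataset.positive_label
    rows = []
    for sc in scenarios:
        scores: dict[str, list] = {"raw": [], "ppdp": []}
        for rep in range(sc.repetitions):
            train, test = make_scenario(dataset, sc, rep)
            rep_cfg = ResampleConfig(
                alpha=config.alpha,
                seed=int(np.random.SeedSequence([config.seed, sc.seed, rep]).generate_state(1)[0] % (2**31)),
                outlier_rule=config.outlier_rule,
                generation_mode=config.generation_mode,
                beta_grid=config.beta_grid,
                quartile_convention=config.quartile_convention,
            )
            try:
                balanced, _ = ppdp_resample(train, rep_cfg)
            except ValueError as exc:
                raise RuntimeError(
                    f"resampling failed in scenario r={sc.r}, N={sc.n_train}, rep={rep}: {exc}"
                ) from exc
            for name, tr in (("raw", train), ("ppdp", balanced)):
                try:
                    pred = _fit_predict(classifier, tr, test)
                except Exception as exc:
                    raise RuntimeError(
                        f"classifier failed in scenario r={sc.r}, N={sc.n_train}, "
                        f"rep={rep}, variant={name}: {exc}"
                    ) from exc
                c = metrics.confusion(test.labels, pred, pos)
                scores[name].append(
                    (metrics.accuracy(c), metrics.g_mean(c), metrics.f_measure(c))
                )
        for name in ("raw", "ppdp"):
            arr = np.array(scores[name])
            rows.append(
                {
                    "r": sc.r,
                    "n_train": sc.n_train,
                    "m_minority": minority_train_size(sc.r, sc.n_train),
                    "method": name,
                    "repetitions": sc.repetitions,
                    "acc": arr[:, 0].mean(),
                    "g_mean": arr[:, 1].mean(),
                    "f1": arr[:, 2].mean(),
                }
            )
    return pd.DataFrame(rows)
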