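import json

import numpy as np
import pandas as pd
import pytest

from ppdp import PPDP, fixtures
from ppdp.resampler import (
    LabeledDataset,
    ResampleConfig,
    oversample_minority,
    ppdp_resample,
    read_table,
    split_by_class,
    undersample_majority,
    write_report,
    write_table,
)


def small_dataset(n_major=57, n_minor=3, seed=11):
    spec = fixtures.FixtureSpec(seed=seed)
    ds = fixtures.make_synthetic_imbalanced(spec)
    tr, _ = fixtures.make_scenario(
        ds, fixtures.ScenarioSpec(r=5, n_train=n_major + n_minor, seed=seed), rep=0
    )
    return tr


class TestSplit:
    def test_majority_minority_counts(self):
        ds = small_dataset()
        minority, majority = split_by_class(ds)
        assert (majority.n_rows, minority.n_rows) == (57, 3)
        assert set(minority.labels) == {1} and set(majority.labels) == {0}

    def test_partition_is_exhaustive(self):
        ds = small_dataset()
        minority, majority = split_by_class(ds)
        assert minority.n_rows + majority.n_rows == ds.n_rows

    def test_tie_uses_declared_positive(self):
        ds = LabeledDataset(np.arange(8.0).reshape(4, 2), [0, 0, 1, 1], ["a", "b"], 1)
        with pytest.warns(UserWarning, match="equal class sizes"):
            minority, _ = split_by_class(ds)
        assert set(minority.labels) == {1}

    def test_non_binary_labels_rejected(self):
        ds = LabeledDataset(np.zeros((3, 1)), [0, 1, 2], ["a"])
        with pytest.raises(ValueError, match="two classes"):
            split_by_class(ds)
        one = LabeledDataset(np.zeros((3, 1)), [1, 1, 1], ["a"])
        with pytest.raises(ValueError, match="two classes"):
            split_by_class(one)


class TestUndersample:
    def test_planted_outlier_lands_in_box_stage(self):
        rng = np.random.default_rng(5)
        X = np.column_stack([rng.uniform(1, 9, 30), rng.uniform(1, 9, 30)])
        X[7, 0] = 100.0
        maj = LabeledDataset(X, np.zeros(30, int), ["a", "b"])
        _, s_box, _, _, removed = undersample_majority(maj, ResampleConfig(alpha=0.0))
        assert 7 in removed["box"]
        assert s_box == len(removed["box"]) >= 1

    def test_count_arithmetic(self):
        _, majority = split_by_class(small_dataset())
        reduced, s_box, s_mtd, models, removed = undersample_majority(majority)
        assert reduced.n_rows == majority.n_rows - s_box - s_mtd
        assert len(removed["box"]) == s_box and len(removed["mtd"]) == s_mtd
        assert set(models) == set(majority.feature_names)
        assert all({"box", "mtd"} <= set(v) for v in models.values())

    def test_wide_domain_alpha_zero_is_identity(self):
        # few points: the diffusion interval easily covers the sample range
        X = np.tile([[2.0], [4.0], [6.0], [8.0]], (1, 2))
        maj = LabeledDataset(X, np.zeros(4, int), ["a", "b"])
        reduced, s_box, s_mtd, _, _ = undersample_majority(maj, ResampleConfig(alpha=0.0))
        assert (s_box, s_mtd) == (0, 0)
        assert np.array_equal(reduced.features, X)

    def test_zero_variance_feature_skips_alpha_cut(self):
        X = np.column_stack([np.full(10, 7.0), np.linspace(2, 8, 10)])
        maj = LabeledDataset(X, np.zeros(10, int), ["const", "x"])
        reduced, _, _, models, _ = undersample_majority(maj, ResampleConfig(alpha=0.0))
        assert models["const"]["mtd"].degenerate
        assert reduced.n_rows == 10

    def test_total_removal_raises(self):
        X = np.column_stack([np.linspace(0, 1, 8), np.linspace(5, 6, 8)])
        maj = LabeledDataset(X, np.zeros(8, int), ["a", "b"])
        with pytest.raises(ValueError, match="lower alpha"):
            undersample_majority(maj, ResampleConfig(alpha=1.0))


class TestOversample:
    def minority(self, m=3):
        rng = np.random.default_rng(2)
        X = np.column_stack([rng.weibull(2.0, m) * 3 + 1, rng.weibull(1.5, m) * 2])
        return LabeledDataset(X, np.ones(m, int), ["a", "b"], 1)

    def test_growth_to_target(self):
        extended, fits = oversample_minority(self.minority(), 37)
        assert extended.n_rows == 40
        assert np.all(extended.labels == 1)
        assert set(fits) == {"a", "b"}

    def test_zero_synthesis_is_identity(self):
        mino = self.minority()
        extended, _ = oversample_minority(mino, 0)
        assert np.array_equal(extended.features, mino.features)

    def test_median_rank_mode_sorted_columns(self):
        extended, _ = oversample_minority(
            self.minority(5), 20, ResampleConfig(generation_mode="median_rank")
        )
        synth = extended.features[5:]
        assert np.all(np.diff(synth, axis=0) >= 0)

    def test_minimum_minority_size(self):
        with pytest.raises(ValueError, match="at least three"):
            oversample_minority(self.minority(2), 5)


class TestPipeline:
    def test_balanced_output_and_report_invariants(self):
        ds = small_dataset()
        balanced, report = ppdp_resample(ds, ResampleConfig(alpha=0.5, seed=9))
        counts = balanced.class_counts()
        assert report.m_major_prime == report.m_major - report.s_box - report.s_mtd
        assert report.n_synthetic == max(report.m_major_prime - report.m_minor, 0)
        assert report.m_minor_prime == report.m_minor + report.n_synthetic
        if report.m_major_prime > report.m_minor:
            assert counts[0] == counts[1] == report.m_major_prime

    def test_same_seed_bit_identical(self):
        ds = small_dataset()
        b1, _ = ppdp_resample(ds, ResampleConfig(seed=4))
        b2, _ = ppdp_resample(ds, ResampleConfig(seed=4))
        assert np.array_equal(b1.features, b2.features)
        assert np.array_equal(b1.labels, b2.labels)

    def test_majority_rows_are_original_rows(self):
        ds = small_dataset()
        balanced, _ = ppdp_resample(ds, ResampleConfig(seed=1))
        original = {tuple(row) for row in ds.features}
        majority_rows = balanced.features[balanced.labels == 0]
        assert all(tuple(row) in original for row in majority_rows)

    def test_alpha_monotonicity_at_fixed_seed(self):
        _, majority = split_by_class(small_dataset())
        s_mtds, retained = [], []
        for alpha in np.arange(0.0, 1.0, 0.1):
            try:
                reduced, _, s_mtd, _, _ = undersample_majority(
                    majority, ResampleConfig(alpha=float(alpha))
                )
                kept = reduced.n_rows
            except ValueError:
                kept, s_mtd = 0, None
            if s_mtd is not None:
                s_mtds.append(s_mtd)
            retained.append(kept)
        assert all(a >= b for a, b in zip(retained, retained[1:]))
        assert all(a <= b for a, b in zip(s_mtds, s_mtds[1:]))


class TestIO:
    def test_round_trip(self, tmp_path):
        ds = small_dataset()
        path = tmp_path / "data.csv"
        write_table(ds, path, label_column="class")
        back = read_table(path, "class", positive_label=1)
        assert np.array_equal(back.features, ds.features)
        assert np.array_equal(back.labels, ds.labels)

    def test_three_classes_rejected(self, tmp_path):
        path = tmp_path / "three.csv"
        pd.DataFrame({"x": [1.0, 2.0, 3.0], "class": [0, 1, 2]}).to_csv(path, index=False)
        with pytest.raises(ValueError, match="two classes"):
            read_table(path, "class")

    def test_missing_value_is_located(self, tmp_path):
        path = tmp_path / "gap.csv"
        pd.DataFrame({"x": [1.0, None, 3.0], "class": [0, 1, 1]}).to_csv(path, index=False)
        with pytest.raises(ValueError, match="row 1, column 'x'"):
            read_table(path, "class")

    def test_missing_label_column(self, tmp_path):
        path = tmp_path / "nolabel.csv"
        pd.DataFrame({"x": [1.0, 2.0]}).to_csv(path, index=False)
        with pytest.raises(ValueError, match="label column"):
            read_table(path, "y")

    def test_report_serializes_to_json(self, tmp_path):
        _, report = ppdp_resample(small_dataset(), ResampleConfig(seed=2))
        path = tmp_path / "report.json"
        write_report(report, path)
        data = json.loads(path.read_text())
        assert data["m_major"] == 57 and data["m_minor"] == 3
        assert "per_feature" in data and "removed_row_ids" in data


class TestModelSurface:
    def test_from_dataframe_fit_summary(self):
        ds = small_dataset()
        df = ds.to_dataframe("label")
        res = PPDP.from_dataframe(df, "label", positive_label=1).fit(alpha=0.5, seed=3)
        text = res.summary()
        assert "majority M:             57" in text
        assert "minority m:             3" in text
        params = res.weibull_params()
        assert set(params["feature"]) == set(ds.feature_names)
        assert (params["beta"] > 0).all() and (params["lamda"] > 0).all()

    def test_results_dataframe_matches_balanced(self):
        ds = small_dataset()
        res = PPDP(ds.features, ds.labels, ds.feature_names, 1).fit(seed=3)
        out = res.to_dataframe()
        assert len(out) == res.balanced.n_rows
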