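"""Feature-table QC: log transform, batch removal, filtering, standardization."""

import numpy as np
import pytest

from metabomr import preprocess
from metabomr.exceptions import ConfigurationError, DataError

from conftest import make_feature_table


class TestLogTransform:
    def test_known_values(self):
        t = make_feature_table(np.full((4, 3), np.e))
        out = preprocess.log_transform(t)
        np.testing.assert_allclose(out.intensities, 1.0)

    def test_ones_to_zeros(self):
        t = make_feature_table(np.ones((4, 3)))
        out = preprocess.log_transform(t)
        np.testing.assert_allclose(out.intensities, 0.0)

    def test_zero_pseudo_count_half_minimum(self):
        x = np.array([[0.0, 4.0], [2.0, 4.0], [8.0, 4.0]])
        out = preprocess.log_transform(make_feature_table(x))
        # zero replaced by half the feature's min positive value (1.0)
        assert out.intensities.iloc[0, 0] == pytest.approx(np.log(1.0))

    def test_negative_intensity_rejected(self):
        x = np.ones((3, 2))
        x[0, 0] = -1.0
        with pytest.raises(DataError):
            make_feature_table(x)

    def test_missing_preserved(self):
        x = np.ones((3, 2))
        x[1, 1] = np.nan
        out = preprocess.log_transform(make_feature_table(x))
        assert np.isnan(out.intensities.iloc[1, 1])


class TestAnovaStandardize:
    def test_no_batch_structure_is_identity(self):
        rng = np.random.default_rng(0)
        x = rng.normal(10, 1, (20, 5))
        t = make_feature_table(x, log_scale=True)
        out = preprocess.anova_standardize(t, factors=(), order_col=None)
        np.testing.assert_allclose(out.intensities, x, atol=1e-10)

    def test_plate_offsets_removed(self):
        rng = np.random.default_rng(1)
        base = rng.normal(10, 1, (20, 4))
        plates = ["p1"] * 10 + ["p2"] * 10
        x = base + np.where(np.arange(20)[:, None] < 10, 1.0, -1.0)
        out = preprocess.anova_standardize(
            make_feature_table(x, plates=plates, log_scale=True), order_col=None)
        arr = out.intensities.to_numpy()
        # post-adjustment per-plate means agree
        np.testing.assert_allclose(arr[:10].mean(axis=0), arr[10:].mean(axis=0), atol=1e-8)

    def test_linear_drift_removed(self):
        rng = np.random.default_rng(2)
        order = np.arange(30)
        x = rng.normal(10, 0.2, (30, 3)) + 0.01 * order[:, None]
        out = preprocess.anova_standardize(
            make_feature_table(x, order=order, log_scale=True), factors=())
        arr = out.intensities.to_numpy()
        oc = order - order.mean()
        slope = oc @ arr / (oc @ oc)
        np.testing.assert_allclose(slope, 0.0, atol=1e-10)

    def test_idempotent(self):
        rng = np.random.default_rng(3)
        x = rng.normal(10, 1, (24, 6)) + np.repeat([0, 1.5], 12)[:, None]
        t = make_feature_table(x, plates=["a"] * 12 + ["b"] * 12, log_scale=True)
        once = preprocess.anova_standardize(t)
        twice = preprocess.anova_standardize(once)
        np.testing.assert_allclose(once.intensities, twice.intensities, atol=1e-10)

    def test_single_sample_level_warns(self):
        x = np.ones((5, 2)) * 10
        t = make_feature_table(x, plates=["a", "a", "a", "a", "b"], log_scale=True)
        with pytest.warns(UserWarning, match="single-sample"):
            preprocess.anova_standardize(t, order_col=None)


class TestFilterFeatures:
    def test_retention_time_rule(self):
        x = np.exp(np.random.default_rng(4).normal(10, 1, (10, 3)))
        t = make_feature_table(x, rt=[34.0, 35.0, 200.0])
        out, report = preprocess.filter_features(t, min_rt=35.0, min_dup_corr=None,
                                                 outlier_sd=None)
        assert list(out.features["id"]) == ["f1", "f2"]
        row = report[report["reason"] == "retention_time"]
        assert list(row["feature_id"]) == ["f0"] and float(row["value"].iloc[0]) == 34.0

    def test_outlier_masked_to_missing(self):
        rng = np.random.default_rng(5)
        x = rng.normal(10, 1, (50, 1))
        x[0, 0] = x[1:, 0].mean() + 4 * x[1:, 0].std(ddof=1)
        t = make_feature_table(np.exp(x), log_scale=False)
        tl = preprocess.log_transform(t)
        out, report = preprocess.filter_features(tl, min_rt=None, min_dup_corr=None,
                                                 outlier_sd=3.0)
        assert np.isnan(out.intensities.iloc[0, 0])
        assert (report["reason"] == "outlier_masked").any()

    def test_all_filters_disabled_identity(self, feature_table):
        out, report = preprocess.filter_features(feature_table, min_rt=None,
                                                 min_dup_corr=None, outlier_sd=None,
                                                 min_nonmissing=None)
        assert out.n_features == feature_table.n_features
        assert len(report) == 0

    def test_duplicate_correlation_removes_noise_features(self):
        from metabomr import simdata
        t = simdata.simulate_feature_table(n_samples=60, n_features=100,
                                           frac_noise_features=0.2,
                                           frac_early_rt=0.0, missing_rate=0.0, seed=6)
        tl = preprocess.log_transform(t)
        out, report = preprocess.filter_features(tl, min_rt=None, min_dup_corr=0.5,
                                                 outlier_sd=None)
        removed = set(report.loc[report["reason"] == "duplicate_correlation", "feature_id"])
        assert len(removed) > 5  # noise features collapse between duplicates
        assert out.n_features + len(removed) == 100

    def test_correlation_filter_without_duplicates_errors(self):
        x = np.exp(np.random.default_rng(7).normal(10, 1, (6, 3)))
        t = make_feature_table(x)
        t.sample_meta.drop(columns="duplicate_pair", inplace=True)
        with pytest.raises(ConfigurationError):
            preprocess.filter_features(t, min_dup_corr=0.5)

    def test_report_accounts_for_each_removed_feature_once(self, feature_table):
        tl = preprocess.log_transform(feature_table)
        out, report = preprocess.filter_features(tl, min_rt=35.0, min_dup_corr=0.5,
                                                 outlier_sd=3.0, min_nonmissing=30)
        removed = report[report["reason"] != "outlier_masked"]
        assert removed["feature_id"].is_unique
        assert out.n_features + len(removed) == feature_table.n_features


class TestStandardize:
    def test_exact_moments(self):
        import pandas as pd
        df = pd.DataFrame({"a": [1.0, 2.0, 3.0]})
        z = preprocess.standardize(df)
        assert z["a"].mean() == pytest.approx(0.0)
        assert z["a"].std(ddof=1) == pytest.approx(1.0)

    def test_constant_feature_dropped_with_warning(self):
        import pandas as pd
        df = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [5.0, 5.0, 5.0]})
        with pytest.warns(UserWarning):
            z = preprocess.standardize(df)
        assert list(z.columns) == ["a"]

    def test_idempotent(self):
        import pandas as pd
        rng = np.random.default_rng(8)
        df = pd.DataFrame(rng.normal(3, 2, (30, 4)))
        df.columns = [str(c) for c in df.columns]
        once = preprocess.standardize(df)
        twice = preprocess.standardize(once)
        np.testing.assert_allclose(once, twice, atol=1e-12)
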