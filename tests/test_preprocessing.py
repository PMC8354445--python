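"""Trend/stationarity tests and the three imputation paths."""

import numpy as np
import pandas as pd
import pytest

from burdenssm import preprocessing as pp


class TestMannKendall:
    def test_strictly_increasing_gives_max_statistic(self):
        res = pp.mann_kendall_test([1, 2, 3, 4, 5])
        assert res.statistic == 10  # n(n-1)/2 concordant pairs

    def test_all_equal_series(self):
        res = pp.mann_kendall_test([2, 2, 2, 2])
        assert res.statistic == 0 and res.p_value == 1.0

    def test_detects_linear_trend(self):
        rng = np.random.default_rng(0)
        x = np.arange(28) + 0.5 * rng.standard_normal(28)
        assert pp.mann_kendall_test(x).p_value < 0.001

    def test_missing_entries_skipped(self):
        x = np.array([1.0, np.nan, 2.0, 3.0, np.nan, 4.0])
        res = pp.mann_kendall_test(x)
        assert res.statistic == 6  # 4 observed points, all concordant

    def test_too_short_raises(self):
        with pytest.raises(ValueError):
            pp.mann_kendall_test([1.0, 2.0, np.nan, np.nan])


class TestSieveBootstrap:
    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            pp.sieve_bootstrap_trend_test(np.arange(5.0))

    def test_detects_strong_trend(self):
        rng = np.random.default_rng(1)
        x = np.arange(28.0) + 0.1 * rng.standard_normal(28)
        res = pp.sieve_bootstrap_trend_test(x, n_boot=499, seed=2)
        assert res.p_value < 0.01

    def test_affine_invariance(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal(50)
        p1 = pp.sieve_bootstrap_trend_test(x, n_boot=199, seed=7).p_value
        p2 = pp.sieve_bootstrap_trend_test(4.0 * x - 2.0, n_boot=199, seed=7).p_value
        assert p1 == p2

    def test_n_boot_floor(self):
        with pytest.raises(ValueError):
            pp.sieve_bootstrap_trend_test(np.arange(20.0), n_boot=50)


class TestADF:
    def test_random_walk_not_rejected(self):
        rng = np.random.default_rng(4)
        assert pp.adf_test(np.cumsum(rng.standard_normal(200))).p_value > 0.10

    def test_iid_rejected(self):
        rng = np.random.default_rng(4)
        assert pp.adf_test(rng.standard_normal(200)).p_value < 0.05

    def test_constant_series_degenerate(self):
        with pytest.raises(ValueError):
            pp.adf_test(np.ones(50))


class TestIntegrationOrder:
    def test_orders_on_cumulative_sums(self):
        rng = np.random.default_rng(5)
        z = rng.standard_normal(200)
        assert pp.integration_order(z) == 0
        assert pp.integration_order(np.cumsum(z)) == 1
        assert pp.integration_order(np.cumsum(np.cumsum(z))) == 2

    def test_monotone_under_cumsum(self):
        rng = np.random.default_rng(6)
        z = rng.standard_normal(200)
        assert pp.integration_order(np.cumsum(z)) >= pp.integration_order(z)

    def test_max_d_flag(self):
        # a double random walk cannot be stationarized with max_d=1
        rng = np.random.default_rng(7)
        z = np.cumsum(np.cumsum(rng.standard_normal(200)))
        assert pp.integration_order(z, max_d=1) == 2


class TestInterpolation:
    def test_midpoint(self):
        assert np.allclose(
            pp.linear_interpolate([1.0, np.nan, 3.0]), [1.0, 2.0, 3.0]
        )

    def test_identity_when_complete(self):
        x = np.array([2.0, 5.0, 1.0])
        assert np.array_equal(pp.linear_interpolate(x), x)

    def test_endpoint_extension(self):
        assert np.allclose(
            pp.linear_interpolate([np.nan, 2.0, 4.0]), [2.0, 2.0, 4.0]
        )

    def test_single_observed_raises(self):
        with pytest.raises(ValueError):
            pp.linear_interpolate([np.nan, 1.0, np.nan])


class TestMeanImpute:
    def test_mean_fill(self):
        assert np.allclose(pp.mean_impute([1.0, np.nan, 3.0]), [1.0, 2.0, 3.0])

    def test_identity_when_complete(self):
        x = np.array([1.0, 9.0])
        assert np.array_equal(pp.mean_impute(x), x)

    def test_threshold_enforced(self):
        with pytest.raises(ValueError, match="40%"):
            pp.mean_impute([1.0, np.nan, np.nan, 2.0])


class TestEMB:
    def _mvn_panel(self, n=120, miss=0.2, seed=0):
        rng = np.random.default_rng(seed)
        A = rng.standard_normal((5, 5)) * 0.4
        cov = A @ A.T + np.eye(5)
        data = rng.multivariate_normal(np.zeros(5), cov, size=n)
        mask = rng.random(data.shape) < miss
        mask[:, 0] = False  # keep one column complete
        incomplete = data.copy()
        incomplete[mask] = np.nan
        return pd.DataFrame(incomplete, columns=list("abcde")), data, mask

    def test_no_missing_gives_identical_copies(self):
        df = pd.DataFrame(np.random.default_rng(1).standard_normal((30, 3)))
        out = pp.emb_multiple_impute(df, m=3, seed=0)
        assert out.m == 3
        for panel in out.panels:
            assert panel.equals(df)

    def test_observed_cells_never_altered(self):
        df, data, mask = self._mvn_panel()
        out = pp.emb_multiple_impute(df, m=5, seed=1)
        for panel in out.panels:
            vals = panel.to_numpy()
            assert not np.isnan(vals).any()
            assert np.array_equal(vals[~mask], data[~mask])

    def test_between_imputation_variance_positive(self):
        df, _, mask = self._mvn_panel()
        out = pp.emb_multiple_impute(df, m=5, seed=2)
        imputed = np.array([panel.to_numpy()[mask] for panel in out.panels])
        assert np.all(imputed.var(axis=0).mean() > 0)

    def test_imputed_cells_track_truth(self):
        # under MCAR the conditional-draw imputations are centred near truth
        df, data, mask = self._mvn_panel(n=200, seed=3)
        out = pp.emb_multiple_impute(df, m=5, seed=3)
        pooled = np.mean([panel.to_numpy()[mask] for panel in out.panels], axis=0)
        err = pooled - data[mask]
        assert abs(err.mean()) < 3 * err.std(ddof=1) / np.sqrt(len(err))

    def test_single_column_rejected(self):
        with pytest.raises(ValueError):
            pp.emb_multiple_impute(pd.DataFrame({"a": [1.0, 2.0]}), m=2)


class TestStandardize:
    def test_observed_moments_and_round_trip(self):
        rng = np.random.default_rng(8)
        df = pd.DataFrame(rng.standard_normal((20, 3)) * 5 + 2, columns=list("xyz"))
        df.iloc[3, 1] = np.nan
        out, params = pp.standardize(df)
        assert np.allclose(out.mean(skipna=True), 0.0, atol=1e-12)
        assert np.allclose(out.std(skipna=True, ddof=1), 1.0, atol=1e-12)
        restored = out * params["sd"] + params["mean"]
        assert np.allclose(restored.to_numpy(), df.to_numpy(), equal_nan=True)

    def test_constant_series_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            pp.standardize(pd.DataFrame({"a": [1.0, 1.0, 1.0], "b": [1.0, 2.0, 3.0]}))
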