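"""Model primitives and the exact Kalman oracle."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import norm

from burdenssm.ssm_core import (
    PARAM_NAMES,
    CovariateSet,
    PriorConfig,
    SSMDataset,
    SSMParameters,
    kalman_exact,
    log_prior,
    measure,
    transition,
)


def make_params(**over):
    base = dict(
        alpha=np.array([0.6, 0.3, 0.2, 0.4, 0.1]),
        theta=np.array([0.7, -0.4, 0.5, 0.3, -0.6, 0.6, 0.2]),
        sigma_s2=0.5,
        sigma_m2=np.array([0.3, 0.4, 0.35]),
    )
    base.update(over)
    return SSMParameters(**base)


class TestEquations:
    def test_transition_direct_substitution(self):
        p = make_params(alpha=np.array([0.3, 0.05, 0.2, 0.9, 0.25]))
        out = transition(1.0, np.ones(4), p, noise=0.0)
        assert np.isclose(out, 1.70)

    def test_transition_pure_persistence(self):
        p = make_params(alpha=np.array([1.0, 0, 0, 0, 0]))
        assert transition(2.5, np.ones(4), p) == 2.5

    def test_measure_direct_substitution(self):
        p = make_params(theta=np.array([0.5, -0.2, 0.8, 0.3, -0.4, 0.7, 0.2]))
        y = measure(1.0, np.ones(3), p)
        assert np.allclose(y, (0.5, 0.9, 0.5))

    def test_measure_identity_loading(self):
        p = make_params(theta=np.array([1.0, 0, 0, 0, 0, 0, 0]))
        x = np.array([0.3, -1.2])
        y1, _, _ = measure(x, np.zeros(3), p)
        assert np.array_equal(y1, x)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        a=st.floats(0.0, 1.0),
        s1=st.floats(-2.0, 2.0),
        s2=st.floats(-2.0, 2.0),
    )
    def test_affinity_of_transition_and_measure(self, a, s1, s2):
        p = make_params()
        u, z = np.ones(4) * 0.5, np.ones(3) * 0.5
        mix = a * s1 + (1 - a) * s2
        assert np.isclose(
            transition(mix, u, p),
            a * transition(s1, u, p) + (1 - a) * transition(s2, u, p),
        )
        ym = measure(mix, z, p)
        y1 = measure(s1, z, p)
        y2 = measure(s2, z, p)
        assert np.allclose(ym, [a * v1 + (1 - a) * v2 for v1, v2 in zip(y1, y2)])


class TestPrior:
    def test_mid_support_log_density(self, prior):
        p = make_params(
            alpha=np.full(5, 0.5),
            theta=np.array([0.5, 0.0, 0.5, 0.5, 0.0, 0.5, 0.5]),
            sigma_s2=0.8,
            sigma_m2=np.full(3, 0.8),
        )
        expected = -(10 * np.log(1.0) + 2 * np.log(2.0) + 4 * np.log(1.4))
        assert np.isclose(log_prior(p, prior), expected)

    def test_out_of_support(self, prior):
        p = make_params(theta=np.array([1.2, 0, 0.5, 0.5, 0, 0.5, 0.5]))
        assert log_prior(p, prior) == -np.inf

    def test_negative_utilization_loading_in_support(self, prior):
        p = make_params(
            alpha=np.full(5, 0.5),
            theta=np.array([0.5, -0.5, 0.5, 0.5, -0.5, 0.5, 0.5]),
            sigma_s2=0.8,
            sigma_m2=np.full(3, 0.8),
        )
        assert np.isfinite(log_prior(p, prior))

    def test_free_subset_restriction(self, prior):
        # only the named coordinates are checked / counted
        p = make_params(sigma_s2=5.0)  # out of support, but not in the subset
        assert np.isfinite(log_prior(p, prior, names=("theta1",)))


def _toy_dataset(T=3, seed=42, mask=None):
    rng = np.random.default_rng(seed)
    cov = CovariateSet(*[rng.standard_normal(T) for _ in range(7)])
    y = rng.standard_normal((3, T))
    if mask is not None:
        y[mask] = np.nan
    return SSMDataset(
        years=np.arange(T), covariates=cov, y1=y[0], y2=y[1], y3=y[2]
    )


class TestKalman:
    def test_matches_brute_force_integration(self):
        # T=3 with one missing cell; the joint likelihood is a 3-dim integral
        ds = _toy_dataset(mask=(np.array([1]), np.array([2])))
        p = make_params()
        kr = kalman_exact(ds, p)
        y, U, Z = ds.indicators(), ds.covariates.state_covariates(), \
            ds.covariates.measurement_covariates()
        th, c = p.theta, ds.covariates.state_covariates() @ p.alpha[1:]

        def obs_lik(xg, t):
            lik = np.ones_like(xg)
            preds = [
                th[0] * xg,
                th[1] * xg + th[2] * Z[t, 1] + th[3] * Z[t, 2],
                th[4] * xg + th[5] * Z[t, 0] + th[6] * Z[t, 2],
            ]
            for j in range(3):
                if not np.isnan(y[j, t]):
                    lik *= norm.pdf(y[j, t], preds[j], np.sqrt(p.sigma_m2[j]))
            return lik

        x1 = np.linspace(-3, 3, 1501)
        xg = np.linspace(-15, 15, 3001)
        ss = np.sqrt(p.sigma_s2)
        M3 = norm.pdf(xg[None, :], p.alpha[0] * xg[:, None] + c[2], ss)
        I3 = np.trapezoid(M3 * obs_lik(xg, 2)[None, :], xg, axis=1)
        M2 = norm.pdf(xg[None, :], p.alpha[0] * x1[:, None] + c[1], ss)
        I2 = np.trapezoid(M2 * (obs_lik(xg, 1) * I3)[None, :], xg, axis=1)
        brute = np.log(np.trapezoid(I2 / 6.0, x1))
        assert abs(brute - kr.log_likelihood) < 1e-6

    def test_noiseless_y1_pins_filtered_mean(self):
        T = 8
        ds = _toy_dataset(T=T, seed=1, mask=(np.array([1, 2]).repeat(T),
                                             np.tile(np.arange(T), 2)))
        p = make_params(
            theta=np.array([1.0, 0, 0, 0, 0, 0, 0]),
            sigma_m2=np.array([1e-10, 0.3, 0.3]),
        )
        kr = kalman_exact(ds, p)
        assert np.allclose(kr.filtered_mean[1:], ds.y1[1:], atol=1e-4)

    def test_steady_state_riccati_fixed_point(self):
        # univariate sub-model (y1 only): filtered variance converges to the
        # positive root of P = r(a^2 P + q)/(a^2 P + q + r)
        T = 40
        mask = (np.array([1, 2]).repeat(T), np.tile(np.arange(T), 2))
        ds = _toy_dataset(T=T, seed=2, mask=mask)
        a, q, r = 0.5, 1.0, 1.0
        p = make_params(
            alpha=np.array([a, 0, 0, 0, 0]),
            theta=np.array([1.0, 0, 0, 0, 0, 0, 0]),
            sigma_s2=q,
            sigma_m2=np.array([r, 1.0, 1.0]),
        )
        kr = kalman_exact(ds, p)
        # solve the scalar Riccati fixed point
        from scipy.optimize import brentq

        f = lambda P: r * (a**2 * P + q) / (a**2 * P + q + r) - P
        P_star = brentq(f, 0.0, 10.0)
        assert abs(kr.filtered_var[-1] - P_star) < 1e-6

    def test_full_mask_gives_zero_loglik_and_mean_recursion(self):
        T = 6
        mask = (np.repeat(np.arange(3), T), np.tile(np.arange(T), 3))
        ds = _toy_dataset(T=T, seed=3, mask=mask)
        p = make_params()
        kr = kalman_exact(ds, p)
        assert kr.log_likelihood == 0.0
        c = ds.covariates.state_covariates() @ p.alpha[1:]
        m = 0.0  # E[U(-3,3)] = 0
        for t in range(1, T):
            m = p.alpha[0] * m + c[t]
            assert np.isclose(kr.filtered_mean[t], m, atol=1e-10)

    def test_masking_is_causal(self):
        ds_full = _toy_dataset(T=10, seed=4)
        t0 = 6
        mask = (np.array([0, 1, 2]), np.array([t0, t0, t0]))
        ds_masked = _toy_dataset(T=10, seed=4, mask=mask)
        p = make_params()
        full = kalman_exact(ds_full, p)
        masked = kalman_exact(ds_masked, p)
        assert np.allclose(full.filtered_mean[:t0], masked.filtered_mean[:t0])
        assert not np.allclose(full.filtered_mean[t0:], masked.filtered_mean[t0:])

    def test_nonpositive_variance_rejected(self):
        ds = _toy_dataset()
        with pytest.raises(ValueError):
            kalman_exact(ds, make_params(sigma_s2=0.0))


class TestParameterVector:
    def test_round_trip_and_names(self):
        p = make_params()
        vec = p.to_vector()
        assert len(vec) == len(PARAM_NAMES) == 16
        back = SSMParameters.from_vector(vec)
        assert np.array_equal(back.to_vector(), vec)
        d = p.to_dict()
        assert d["theta2"] == p.theta[1] and d["sigma_m2_3"] == p.sigma_m2[2]
        assert np.array_equal(SSMParameters.from_dict(d).to_vector(), vec)

    def test_json_round_trip(self, tmp_path):
        p = make_params()
        p.to_json(tmp_path / "p.json")
        assert np.array_equal(
            SSMParameters.from_json(tmp_path / "p.json").to_vector(), p.to_vector()
        )

    def test_bad_shapes_rejected(self):
        with pytest.raises(ValueError):
            SSMParameters(alpha=np.zeros(4), theta=np.zeros(7),
                          sigma_s2=1.0, sigma_m2=np.zeros(3))


def test_prior_config_validation():
    with pytest.raises(ValueError):
        PriorConfig(bounds={**PriorConfig().bounds, "theta1": (1.0, 0.0)})
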