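"""Sequential Monte Carlo: weights, resampling, jitter, and both filters."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from burdenssm.particle_filter import (
    compute_weights,
    init_particles,
    jitter_parameters,
    pf_likelihood,
    pf_online,
    resample,
)
from burdenssm.ssm_core import PriorConfig, kalman_exact, log_prior, SSMParameters
from conftest import mask_all


class TestInit:
    def test_particles_inside_prior_support(self, prior):
        ens = init_particles(200, prior, seed=1)
        assert np.all((ens.x > -3) & (ens.x < 3))
        for row in ens.params[:20]:
            p = SSMParameters.from_vector(row)
            assert np.isfinite(log_prior(p, prior))

    def test_initial_weights_uniform(self, prior):
        ens = init_particles(50, prior, seed=1)
        assert np.allclose(ens.normalized_weights, 1 / 50)

    def test_invalid_size(self, prior):
        with pytest.raises(ValueError):
            init_particles(0, prior)


class TestWeights:
    def test_all_missing_gives_unit_raw_and_uniform_normalized(self):
        raw, norm = compute_weights(
            np.array([np.nan] * 3), np.zeros((40, 3)), np.ones(3)
        )
        assert np.array_equal(raw, np.ones(40))
        assert np.array_equal(norm, np.full(40, 1 / 40))

    def test_gaussian_mode_value(self):
        # a particle predicting the observation exactly, unit variances
        y = np.array([0.2, -0.1, 0.4])
        preds = np.vstack([y, y + 1.0])
        raw, _ = compute_weights(y, preds, np.ones(3))
        assert np.isclose(raw[0], (2 * np.pi) ** (-1.5))

    def test_normalized_weights_sum_to_one(self):
        rng = np.random.default_rng(0)
        raw, norm = compute_weights(
            rng.standard_normal(3), rng.standard_normal((100, 3)), np.full(3, 0.5)
        )
        assert np.isclose(norm.sum(), 1.0)

    def test_underflow_falls_back_to_log_space(self):
        y = np.array([1000.0, np.nan, np.nan])
        preds = np.zeros((10, 3))
        preds[0, 0] = 1.0  # least-bad particle
        with pytest.warns(RuntimeWarning, match="underflow"):
            raw, norm = compute_weights(y, preds, np.full(3, 0.01))
        assert np.isclose(norm.sum(), 1.0)
        assert norm[0] > 0.99

    def test_nonpositive_variance_rejected(self):
        with pytest.raises(ValueError):
            compute_weights(np.zeros(3), np.zeros((5, 3)), np.array([1.0, 0.0, 1.0]))


class TestResample:
    def test_degenerate_weight_copies_one_particle(self, prior):
        ens = init_particles(30, prior, seed=2)
        v = np.zeros(30)
        v[7] = 1.0
        ens.normalized_weights = v
        out = resample(ens, seed=3)
        assert np.all(out.x == ens.x[7])
        assert np.all(out.params == ens.params[7])

    def test_size_preserved_and_weights_reset(self, prior):
        ens = init_particles(64, prior, seed=2)
        out = resample(ens, seed=3)
        assert out.N == 64
        assert np.allclose(out.normalized_weights, 1 / 64)

    def test_uniform_weights_expected_offspring(self):
        # under uniform weights each index expects one offspring per draw
        from burdenssm.particle_filter import _resample_indices

        N, reps = 50, 400
        v = np.full(N, 1.0 / N)
        counts = np.zeros(N)
        for s in range(reps):
            idx = _resample_indices(v, np.random.default_rng(s), "multinomial")
            counts += np.bincount(idx, minlength=N)
        mean_offspring = counts / reps
        # binomial(N, 1/N) has sd ~ 1, so the per-index MC error is 1/sqrt(reps)
        assert np.all(np.abs(mean_offspring - 1.0) < 5 / np.sqrt(reps))

    def test_systematic_scheme_supported(self, prior):
        ens = init_particles(16, prior, seed=5)
        out = resample(ens, seed=6, scheme="systematic")
        assert out.N == 16


class TestJitter:
    def test_zero_variance_is_identity(self, prior):
        ens = init_particles(20, prior, seed=7)
        out = jitter_parameters(ens, jitter_variance=0.0, seed=8, prior=prior)
        assert np.array_equal(out.params, ens.params)

    def test_default_variance_comes_from_prior(self, prior):
        assert prior.jitter_variance == 0.01

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_reflection_keeps_support(self, seed, prior):
        ens = init_particles(50, prior, seed=seed)
        out = jitter_parameters(ens, jitter_variance=0.5, seed=seed, prior=prior)
        b = prior.bounds_array()
        assert np.all(out.params >= b[:, 0]) and np.all(out.params <= b[:, 1])
        assert np.all(out.params[:, 12:] > 0)  # variances stay positive

    def test_fixed_parameter_ensemble_rejected(self, prior):
        ens = init_particles(10, prior, seed=0, online=False)
        with pytest.raises(ValueError):
            jitter_parameters(ens, seed=0, prior=prior)


class TestLikelihoodFilter:
    def test_full_mask_gives_exactly_zero(self, study_t10):
        _, ds, _ = study_t10
        ll, xhat = pf_likelihood(mask_all(ds), _mid_params(), N=100, seed=1)
        assert ll == 0.0
        assert len(xhat) == len(ds)

    def test_seeded_bit_reproducibility(self, study_t10, true_params):
        _, ds, _ = study_t10
        a = pf_likelihood(ds, true_params, N=200, seed=9)
        b = pf_likelihood(ds, true_params, N=200, seed=9)
        assert a[0] == b[0] and np.array_equal(a[1], b[1])

    def test_estimator_variance_shrinks_with_particles(self, study_t10, true_params):
        _, ds, _ = study_t10
        small = [pf_likelihood(ds, true_params, N=100, seed=s)[0] for s in range(30)]
        large = [pf_likelihood(ds, true_params, N=1000, seed=s)[0] for s in range(30)]
        assert np.var(large, ddof=1) < np.var(small, ddof=1)

    def test_filtered_mean_tracks_kalman(self, study_t10, true_params):
        _, ds, _ = study_t10
        kr = kalman_exact(ds, true_params)
        _, xhat = pf_likelihood(ds, true_params, N=4000, seed=3)
        rmse = np.sqrt(np.mean((xhat - kr.filtered_mean) ** 2))
        assert rmse < 0.1


class TestOnlineFilter:
    def test_trajectory_contract(self, study_t28):
        _, ds, _ = study_t28
        res = pf_online(ds, N=300, seed=1)
        T = len(ds)
        assert res.state_trajectory.shape == (T,)
        assert res.parameter_trajectories.shape == (T, 16)

    def test_no_jitter_single_particle_freezes_parameters(self, study_t10):
        _, ds, _ = study_t10
        res = pf_online(ds, N=1, seed=2, jitter_variance=0.0)
        assert np.allclose(
            res.parameter_trajectories, res.parameter_trajectories[0][None, :]
        )

    def test_initial_estimate_is_prior_mean_of_particles(self, study_t10, prior):
        _, ds, _ = study_t10
        res = pf_online(ds, N=500, seed=3)
        rng = np.random.default_rng(3)
        x0 = rng.uniform(-3, 3, size=500)
        assert np.isclose(res.state_trajectory[0], x0.mean())

    def test_bit_reproducible(self, study_t10):
        _, ds, _ = study_t10
        a = pf_online(ds, N=100, seed=4)
        b = pf_online(ds, N=100, seed=4)
        assert np.array_equal(a.parameter_trajectories, b.parameter_trajectories)
        assert a.log_likelihood == b.log_likelihood

    def test_parameters_stay_in_prior_support(self, study_t28, prior):
        _, ds, _ = study_t28
        res = pf_online(ds, N=300, seed=5)
        b = prior.bounds_array()
        assert np.all(res.parameter_trajectories >= b[:, 0])
        assert np.all(res.parameter_trajectories <= b[:, 1])


def _mid_params():
    return SSMParameters(
        alpha=np.full(5, 0.5),
        theta=np.array([0.5, -0.2, 0.5, 0.5, -0.2, 0.5, 0.5]),
        sigma_s2=0.5,
        sigma_m2=np.full(3, 0.5),
    )
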