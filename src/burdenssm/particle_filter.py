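"""Sequential Monte Carlo for the burden index.

Two filters are provided:

* :func:`pf_likelihood` - a bootstrap filter over the scalar state at fixed
  parameters.  Its by-product, the sum over time of the log of the mean raw
  weight, is the unbiased likelihood estimate the PIMH sampler relies on.
* :func:`pf_online` - joint state + parameter ("online") estimation: every
  static parameter is given artificial random-walk dynamics with N(0, 0.01)
  jitter, so a single filter sweep tracks the 16 parameters alongside x_t.

Missing-observation rule: an indicator that is missing at time t contributes
a likelihood factor of one (log-weight contribution zero), so a step with no
observations leaves all normalized weights at 1/N and adds exactly zero to
the log-likelihood.  Weights are computed in log space and normalized by
log-sum-exp; resampling is multinomial every step (systematic available).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .ssm_core import (
    PARAM_NAMES,
    PriorConfig,
    SSMDataset,
    SSMParameters,
    _measurement_terms,
)

__all__ = [
    "ParticleEnsemble",
    "OnlineFitResult",
    "init_particles",
    "compute_weights",
    "resample",
    "jitter_parameters",
    "pf_online",
    "pf_likelihood",
]

# parameter-vector column indices (see ssm_core.PARAM_NAMES)
_A = slice(0, 5)          # alpha1..alpha5
_TH = slice(5, 12)        # theta1..theta7
_SS = 12                  # sigma_s2
_SM = slice(13, 16)       # sigma_m2_1..3


@dataclass
class ParticleEnsemble:
    """N joint particles: state x, optional parameter block, and weights."""

    x: np.ndarray
    params: np.ndarray | None  # (N, 16) in online mode, None when fixed
    raw_weights: np.ndarray
    normalized_weights: np.ndarray

    def __post_init__(self) -> None:
        if self.N < 1:
            raise ValueError("ensemble needs at least one particle")
        if np.any(self.raw_weights < 0):
            raise ValueError("raw weights must be nonnegative")
        if abs(self.normalized_weights.sum() - 1.0) > 1e-10:
            raise ValueError("normalized weights must sum to one")

    @property
    def N(self) -> int:
        return len(self.x)


@dataclass
class OnlineFitResult:
    """Joint-filter output: weighted-mean trajectories and the final estimate."""

    state_trajectory: np.ndarray          # (T,)
    parameter_trajectories: np.ndarray    # (T, 16), rows ordered by PARAM_NAMES
    final_parameters: SSMParameters
    log_likelihood: float
    param_names: tuple[str, ...] = PARAM_NAMES


def init_particles(
    N: int, prior: PriorConfig | None = None, seed: int = 0, online: bool = True
) -> ParticleEnsemble:
    """Draw the initial ensemble from the prior with uniform weights.

    x ~ U(-3, 3); in online mode each parameter coordinate is drawn from its
    uniform prior support.
    """
    if N < 1:
        raise ValueError("N must be >= 1")
    prior = prior or PriorConfig()
    rng = np.random.default_rng(seed)
    x = rng.uniform(*prior.x0_support, size=N)
    params = None
    if online:
        b = prior.bounds_array()
        params = rng.uniform(b[:, 0], b[:, 1], size=(N, len(PARAM_NAMES)))
    w = np.ones(N)
    return ParticleEnsemble(
        x=x, params=params, raw_weights=w, normalized_weights=w / N
    )


def compute_weights(y_obs, y_pred, sigmas) -> tuple[np.ndarray, np.ndarray]:
    """Per-particle raw and normalized importance weights at one time step.

    ``y_obs`` is length 3 with NaN marking missing indicators; ``y_pred`` is
    (N, 3) predicted indicator means and ``sigmas`` the measurement variances
    ((3,) shared or (N, 3) per-particle).  Each observed indicator
    contributes its Gaussian density, each missing one a factor of one; the
    raw weight is the product over indicators.  When every raw weight
    underflows to zero the normalization falls back to log space.
    """
    y_obs = np.asarray(y_obs, dtype=float)
    y_pred = np.atleast_2d(np.asarray(y_pred, dtype=float))
    sig = np.asarray(sigmas, dtype=float)
    if np.any(sig <= 0):
        raise ValueError("measurement variances must be positive")
    sig = np.broadcast_to(sig, y_pred.shape)
    N = y_pred.shape[0]
    logw = np.zeros(N)
    for j in range(3):
        if np.isnan(y_obs[j]):
            continue
        s = sig[:, j]
        logw = logw - 0.5 * (np.log(2.0 * np.pi * s) + (y_obs[j] - y_pred[:, j]) ** 2 / s)
    raw = np.exp(logw)
    if raw.sum() == 0.0:
        warnings.warn(
            "all raw weights underflowed; normalizing in log space", RuntimeWarning
        )
        shifted = np.exp(logw - logw.max())
        return raw, shifted / shifted.sum()
    return raw, raw / raw.sum()


def _resample_indices(
    v: np.ndarray, rng: np.random.Generator, scheme: str
) -> np.ndarray:
    N = len(v)
    cdf = np.cumsum(v)
    cdf[-1] = 1.0
    if scheme == "multinomial":
        u = rng.random(N)
    elif scheme == "systematic":
        u = (rng.random() + np.arange(N)) / N
    else:
        raise ValueError(f"unknown resampling scheme '{scheme}'")
    return np.searchsorted(cdf, u, side="left")


def resample(
    ensemble: ParticleEnsemble, seed: int = 0, scheme: str = "multinomial"
) -> ParticleEnsemble:
    """Draw N offspring proportional to the normalized weights; reset to 1/N."""
    rng = np.random.default_rng(seed)
    idx = _resample_indices(ensemble.normalized_weights, rng, scheme)
    w = np.ones(ensemble.N)
    return ParticleEnsemble(
        x=ensemble.x[idx],
        params=None if ensemble.params is None else ensemble.params[idx],
        raw_weights=w,
        normalized_weights=w / ensemble.N,
    )


def _reflect(values: np.ndarray, lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
    width = hi - lo
    y = np.mod(values - lo, 2.0 * width)
    return lo + np.where(y > width, 2.0 * width - y, y)


def jitter_parameters(
    ensemble: ParticleEnsemble,
    jitter_variance: float | None = None,
    seed: int = 0,
    prior: PriorConfig | None = None,
) -> ParticleEnsemble:
    """Artificial parameter dynamics: add N(0, jitter_variance) to every
    parameter coordinate, reflecting at the prior bounds so the ensemble
    stays inside the support (variances in particular remain positive).
    The state coordinate is not jittered - it evolves through the state
    equation."""
    if ensemble.params is None:
        raise ValueError("jitter requires an online (joint) ensemble")
    prior = prior or PriorConfig()
    jv = prior.jitter_variance if jitter_variance is None else jitter_variance
    if jv == 0.0:
        return ensemble
    rng = np.random.default_rng(seed)
    b = prior.bounds_array()
    noise = rng.normal(0.0, np.sqrt(jv), size=ensemble.params.shape)
    params = _reflect(ensemble.params + noise, b[:, 0], b[:, 1])
    return ParticleEnsemble(
        x=ensemble.x,
        params=params,
        raw_weights=ensemble.raw_weights,
        normalized_weights=ensemble.normalized_weights,
    )


def _prepare(dataset: SSMDataset):
    y = dataset.indicators()
    obs = ~np.isnan(y)
    U = dataset.covariates.state_covariates()
    Z = dataset.covariates.measurement_covariates()
    if np.isnan(U).any() or np.isnan(Z).any():
        raise ValueError("covariates must be complete (impute upstream)")
    return y, obs, U, Z


def pf_likelihood(
    dataset: SSMDataset,
    params: SSMParameters,
    N: int = 1000,
    seed: int = 0,
    prior: PriorConfig | None = None,
    resampling: str = "multinomial",
) -> tuple[float, np.ndarray]:
    """Bootstrap filter at fixed parameters; unbiased likelihood estimate.

    Returns ``(log_likelihood, x_hat)`` where the log-likelihood is
    sum over t of log( (1/N) sum_i w_t^(i) ) with contributions from t = 2
    onward, and x_hat is the weighted-mean filtered trajectory (x_hat_1 is
    the unweighted mean of the initial U(-3,3) particles).  Missing
    indicators contribute a factor of one, so a fully masked dataset returns
    exactly zero.
    """
    if params.sigma_s2 <= 0 or np.any(params.sigma_m2 <= 0):
        raise ValueError("noise variances must be positive")
    prior = prior or PriorConfig()
    y, obs, U, Z = _prepare(dataset)
    T = len(dataset)
    a1 = params.alpha[0]
    c = U @ params.alpha[1:]
    h, d, r = _measurement_terms(dataset, params)
    log2pi_r = np.log(2.0 * np.pi * r)
    sd = np.sqrt(params.sigma_s2)

    rng = np.random.default_rng(seed)
    x = rng.uniform(*prior.x0_support, size=N)
    xhat = np.empty(T)
    xhat[0] = x.mean()
    loglik = 0.0
    logN = np.log(N)
    for t in range(1, T):
        x = a1 * x + c[t] + sd * rng.standard_normal(N)
        observed = np.flatnonzero(obs[:, t])
        if observed.size:
            logw = np.zeros(N)
            for j in observed:
                resid = y[j, t] - (h[j] * x + d[j, t])
                logw -= 0.5 * (log2pi_r[j] + resid**2 / r[j])
            mx = logw.max()
            w = np.exp(logw - mx)
            sw = w.sum()
            loglik += mx + np.log(sw) - logN
            v = w / sw
            xhat[t] = v @ x
        else:
            v = np.full(N, 1.0 / N)
            xhat[t] = x.mean()
        idx = _resample_indices(v, rng, resampling)
        x = x[idx]
    return float(loglik), xhat


def pf_online(
    dataset: SSMDataset,
    N: int = 1000,
    seed: int = 0,
    prior: PriorConfig | None = None,
    jitter_variance: float | None = None,
    resampling: str = "multinomial",
) -> OnlineFitResult:
    """Joint state + parameter filtering with artificial parameter dynamics.

    Per time step (t = 2..T): jitter the parameter block, propagate each
    particle's state with its own parameters, predict the indicators, weight
    with the missing-value rule, record the weighted-mean state and parameter
    estimates, and resample.  The t = 1 estimates are the unweighted means of
    the initial prior draws.
    """
    prior = prior or PriorConfig()
    jv = prior.jitter_variance if jitter_variance is None else jitter_variance
    y, obs, U, Z = _prepare(dataset)
    T = len(dataset)
    b = prior.bounds_array()
    lo, hi = b[:, 0], b[:, 1]

    rng = np.random.default_rng(seed)
    x = rng.uniform(*prior.x0_support, size=N)
    S = rng.uniform(lo, hi, size=(N, len(PARAM_NAMES)))

    traj = np.empty(T)
    ptraj = np.empty((T, len(PARAM_NAMES)))
    traj[0] = x.mean()
    ptraj[0] = S.mean(axis=0)
    loglik = 0.0
    logN = np.log(N)
    jsd = np.sqrt(jv)
    for t in range(1, T):
        if jv > 0.0:
            S = _reflect(S + rng.normal(0.0, jsd, size=S.shape), lo, hi)
        x = (
            S[:, 0] * x
            + S[:, 1:5] @ U[t]
            + np.sqrt(S[:, _SS]) * rng.standard_normal(N)
        )
        z1, z2, z3 = Z[t]
        preds = (
            S[:, 5] * x,
            S[:, 6] * x + S[:, 7] * z2 + S[:, 8] * z3,
            S[:, 9] * x + S[:, 10] * z1 + S[:, 11] * z3,
        )
        observed = np.flatnonzero(obs[:, t])
        if observed.size:
            logw = np.zeros(N)
            for j in observed:
                s = S[:, 13 + j]
                logw -= 0.5 * (
                    np.log(2.0 * np.pi * s) + (y[j, t] - preds[j]) ** 2 / s
                )
            mx = logw.max()
            w = np.exp(logw - mx)
            sw = w.sum()
            loglik += mx + np.log(sw) - logN
            v = w / sw
        else:
            v = np.full(N, 1.0 / N)
        traj[t] = v @ x
        ptraj[t] = v @ S
        idx = _resample_indices(v, rng, resampling)
        x = x[idx]
        S = S[idx]
    return OnlineFitResult(
        state_trajectory=traj,
        parameter_trajectories=ptraj,
        final_parameters=SSMParameters.from_vector(ptraj[-1]),
        log_likelihood=float(loglik),
    )
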