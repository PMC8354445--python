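"""Linear-Gaussian state-space model for a latent disease-burden index.

The model tracks a scalar latent burden ``x_t`` for one disease group over
annual time points ``t = 1..T``:

state:        x_t  = a1*x_{t-1} + a2*u1_t + a3*u2_t + a4*u3_t + a5*u4_t + e_t
measurement:  y1_t = th1*x_t                         + n1_t   (years of life lost)
              y2_t = th2*x_t + th3*z2_t + th4*z3_t   + n2_t   (outpatient visits)
              y3_t = th5*x_t + th6*z1_t + th7*z3_t   + n3_t   (hospital days)

with independent Gaussian noises ``e ~ N(0, sigma_s2)`` and
``n_j ~ N(0, sigma_m2_j)``.  The covariates are a risk-factor factor score
(u1), disease prevalence (u2), mild/moderate and severe disability-weight
averages (u3, u4), hospital beds (z1), specialists (z2) and GDP per capita
(z3), all standardized before inference.

The state recursion starts at t = 2; x_1 is drawn from U(-3, 3) and the
observations at t = 1 contribute no likelihood term (this mirrors the
sequential filter, which only weights particles from t = 2 onward, and the
exact Kalman oracle below adopts the same convention so both target the same
marginal likelihood).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from numpy.polynomial.legendre import leggauss
from scipy.special import logsumexp

__all__ = [
    "PARAM_NAMES",
    "SSMParameters",
    "CovariateSet",
    "SSMDataset",
    "LatentTrajectory",
    "PriorConfig",
    "KalmanResult",
    "transition",
    "measure",
    "log_prior",
    "kalman_exact",
]

#: Flat parameter ordering used everywhere a parameter vector appears.
PARAM_NAMES: tuple[str, ...] = (
    "alpha1", "alpha2", "alpha3", "alpha4", "alpha5",
    "theta1", "theta2", "theta3", "theta4", "theta5", "theta6", "theta7",
    "sigma_s2", "sigma_m2_1", "sigma_m2_2", "sigma_m2_3",
)

N_PARAMS = len(PARAM_NAMES)


@dataclass
class SSMParameters:
    """The estimand: state coefficients, measurement loadings and variances.

    ``alpha`` holds (persistence, risk-factor, prevalence, mild/moderate
    weight, severe weight) effects; ``theta`` holds the three indicator
    loadings and the supply/financial-access effects; ``sigma_s2`` is the
    state noise variance and ``sigma_m2`` the three measurement variances.
    """

    alpha: np.ndarray
    theta: np.ndarray
    sigma_s2: float
    sigma_m2: np.ndarray

    def __post_init__(self) -> None:
        self.alpha = np.asarray(self.alpha, dtype=float)
        self.theta = np.asarray(self.theta, dtype=float)
        self.sigma_m2 = np.asarray(self.sigma_m2, dtype=float)
        if self.alpha.shape != (5,):
            raise ValueError(f"alpha must have 5 entries, got {self.alpha.shape}")
        if self.theta.shape != (7,):
            raise ValueError(f"theta must have 7 entries, got {self.theta.shape}")
        if self.sigma_m2.shape != (3,):
            raise ValueError(f"sigma_m2 must have 3 entries, got {self.sigma_m2.shape}")

    def to_vector(self) -> np.ndarray:
        return np.concatenate(
            [self.alpha, self.theta, [self.sigma_s2], self.sigma_m2]
        )

    @classmethod
    def from_vector(cls, vec: np.ndarray) -> "SSMParameters":
        vec = np.asarray(vec, dtype=float)
        if vec.shape != (N_PARAMS,):
            raise ValueError(f"parameter vector must have {N_PARAMS} entries")
        return cls(
            alpha=vec[0:5],
            theta=vec[5:12],
            sigma_s2=float(vec[12]),
            sigma_m2=vec[13:16],
        )

    def to_dict(self) -> dict[str, float]:
        return dict(zip(PARAM_NAMES, self.to_vector().tolist()))

    @classmethod
    def from_dict(cls, d: dict[str, float]) -> "SSMParameters":
        return cls.from_vector(np.array([d[name] for name in PARAM_NAMES]))

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "SSMParameters":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass
class CovariateSet:
    """Exogenous series entering the state and measurement equations.

    Missing values are represented as NaN; inference requires complete
    (imputed) covariates.
    """

    u1: np.ndarray
    u2: np.ndarray
    u3: np.ndarray
    u4: np.ndarray
    z1: np.ndarray
    z2: np.ndarray
    z3: np.ndarray

    def __post_init__(self) -> None:
        for name in ("u1", "u2", "u3", "u4", "z1", "z2", "z3"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        lengths = {len(getattr(self, n)) for n in ("u1", "u2", "u3", "u4", "z1", "z2", "z3")}
        if len(lengths) != 1:
            raise ValueError(f"covariate series have unequal lengths: {lengths}")

    def __len__(self) -> int:
        return len(self.u1)

    def state_covariates(self) -> np.ndarray:
        """(T, 4) matrix [u1, u2, u3, u4] driving the state equation."""
        return np.column_stack([self.u1, self.u2, self.u3, self.u4])

    def measurement_covariates(self) -> np.ndarray:
        """(T, 3) matrix [z1, z2, z3] entering the measurement equations."""
        return np.column_stack([self.z1, self.z2, self.z3])

    def is_complete(self) -> bool:
        return not any(
            np.isnan(getattr(self, n)).any()
            for n in ("u1", "u2", "u3", "u4", "z1", "z2", "z3")
        )


@dataclass
class SSMDataset:
    """Observed indicators plus covariates; NaN in y2/y3 marks missing cells."""

    years: np.ndarray
    covariates: CovariateSet
    y1: np.ndarray
    y2: np.ndarray
    y3: np.ndarray

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years)
        for name in ("y1", "y2", "y3"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        T = len(self.years)
        for name in ("y1", "y2", "y3"):
            if len(getattr(self, name)) != T:
                raise ValueError(f"{name} length {len(getattr(self, name))} != T={T}")
        if len(self.covariates) != T:
            raise ValueError("covariate length does not match years")

    def __len__(self) -> int:
        return len(self.years)

    def indicators(self) -> np.ndarray:
        """(3, T) array of indicators with NaN for missing cells."""
        return np.vstack([self.y1, self.y2, self.y3])

    @property
    def missing_mask(self) -> np.ndarray:
        """(3, T) boolean array, True where an indicator cell is missing."""
        return np.isnan(self.indicators())


@dataclass
class LatentTrajectory:
    """True or estimated burden-index path on the standardized scale."""

    x: np.ndarray

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)

    def __len__(self) -> int:
        return len(self.x)


def _default_bounds() -> dict[str, tuple[float, float]]:
    bounds: dict[str, tuple[float, float]] = {}
    for name in PARAM_NAMES:
        if name in ("theta2", "theta5"):
            bounds[name] = (-1.0, 1.0)
        elif name.startswith("sigma"):
            bounds[name] = (0.1, 1.5)
        else:
            bounds[name] = (0.0, 1.0)
    return bounds


@dataclass
class PriorConfig:
    """Independent uniform priors over the parameter supports.

    Positive coefficients live on (0,1), the two utilization loadings on
    (-1,1), all variances on (0.1, 1.5); the initial burden value on (-3, 3).
    ``jitter_variance`` is the artificial-dynamics noise used by the online
    filter.
    """

    bounds: dict[str, tuple[float, float]] = field(default_factory=_default_bounds)
    x0_support: tuple[float, float] = (-3.0, 3.0)
    jitter_variance: float = 0.01

    def __post_init__(self) -> None:
        for name, (lo, hi) in self.bounds.items():
            if not lo < hi:
                raise ValueError(f"prior bound for {name} has lower >= upper")
        if not self.x0_support[0] < self.x0_support[1]:
            raise ValueError("x0_support has lower >= upper")

    def bounds_array(self, names=PARAM_NAMES) -> np.ndarray:
        """(len(names), 2) array of [lower, upper] rows."""
        return np.array([self.bounds[n] for n in names])


def transition(x_prev, u_t, params: SSMParameters, noise=0.0):
    """State equation: one step of the burden recursion.

    Broadcasts over arrays, so ``x_prev`` may be an ensemble of particles.
    """
    u_t = np.asarray(u_t, dtype=float)
    a = params.alpha
    return a[0] * x_prev + u_t[..., 0] * a[1] + u_t[..., 1] * a[2] \
        + u_t[..., 2] * a[3] + u_t[..., 3] * a[4] + noise


def measure(x_t, z_t, params: SSMParameters, noises=(0.0, 0.0, 0.0)):
    """Measurement equations: indicator means given the state and supplies.

    Returns (y1, y2, y3); broadcasts over particle arrays.
    """
    z_t = np.asarray(z_t, dtype=float)
    th = params.theta
    n = np.asarray(noises, dtype=float)
    y1 = th[0] * x_t + n[..., 0]
    y2 = th[1] * x_t + th[2] * z_t[..., 1] + th[3] * z_t[..., 2] + n[..., 1]
    y3 = th[4] * x_t + th[5] * z_t[..., 0] + th[6] * z_t[..., 2] + n[..., 2]
    return y1, y2, y3


def log_prior(params: SSMParameters, prior: PriorConfig, names=PARAM_NAMES) -> float:
    """Sum of log-uniform densities; -inf outside the support.

    ``names`` restricts the computation to a free-parameter subset (used by
    restricted samplers); fixed coordinates then contribute no term.
    """
    vec = params.to_dict()
    total = 0.0
    for name in names:
        lo, hi = prior.bounds[name]
        v = vec[name]
        if not lo < v < hi:
            return -np.inf
        total -= np.log(hi - lo)
    return total


@dataclass
class KalmanResult:
    filtered_mean: np.ndarray
    filtered_var: np.ndarray
    log_likelihood: float
    loglik_by_time: np.ndarray


def _measurement_terms(dataset: SSMDataset, params: SSMParameters):
    """Per-time measurement loadings h (3,), offsets d (3, T) and variances."""
    Z = dataset.covariates.measurement_covariates()  # columns z1, z2, z3
    th = params.theta
    T = len(dataset)
    d = np.zeros((3, T))
    d[1] = th[2] * Z[:, 1] + th[3] * Z[:, 2]
    d[2] = th[5] * Z[:, 0] + th[6] * Z[:, 2]
    h = np.array([th[0], th[1], th[4]])
    return h, d, params.sigma_m2.copy()


def kalman_exact(
    dataset: SSMDataset, params: SSMParameters, n_quad: int = 128
) -> KalmanResult:
    """Exact filtering and marginal likelihood for the linear-Gaussian model.

    Conditional on the initial state x_1 the model is linear-Gaussian, so the
    uniform U(-3,3) initial law is handled exactly by running one Kalman
    recursion per Gauss-Legendre node of x_1 and mixing the node filters with
    their posterior weights.  Missing indicator cells are skipped in the
    update (their measurement rows dropped at that t), mirroring the particle
    filter's likelihood-one rule, and the observations at t = 1 are not used.
    This is a correctness oracle, not part of the estimation path.
    """
    if params.sigma_s2 <= 0 or np.any(params.sigma_m2 <= 0):
        raise ValueError("kalman_exact requires strictly positive noise variances")
    T = len(dataset)
    y = dataset.indicators()
    obs = ~dataset.missing_mask
    U = dataset.covariates.state_covariates()
    a1 = params.alpha[0]
    c = U @ params.alpha[1:]  # covariate drift per t
    h, d, r = _measurement_terms(dataset, params)

    lo, hi = (-3.0, 3.0)
    nodes, wts = leggauss(n_quad)
    half = (hi - lo) / 2.0
    m = lo + half * (nodes + 1.0)          # node means for x_1 (K,)
    log_mix = np.log(wts * half) - np.log(hi - lo)  # log of U(-3,3) quadrature mass
    P = np.zeros_like(m)
    ll = np.zeros_like(m)                  # running conditional log-lik per node

    filtered_mean = np.empty(T)
    filtered_var = np.empty(T)
    loglik_by_time = np.zeros(T)

    def mixture_moments():
        w = np.exp(log_mix + ll - logsumexp(log_mix + ll))
        mu = float(w @ m)
        var = float(w @ (P + m**2) - mu**2)
        return mu, var

    filtered_mean[0], filtered_var[0] = mixture_moments()
    prev_total = logsumexp(log_mix + ll)
    for t in range(1, T):
        m = a1 * m + c[t]
        P = a1**2 * P + params.sigma_s2
        for j in range(3):
            if not obs[j, t]:
                continue
            v = y[j, t] - (h[j] * m + d[j, t])
            S = h[j] ** 2 * P + r[j]
            K = P * h[j] / S
            m = m + K * v
            P = (1.0 - K * h[j]) * P
            ll = ll - 0.5 * (np.log(2.0 * np.pi * S) + v**2 / S)
        filtered_mean[t], filtered_var[t] = mixture_moments()
        total = logsumexp(log_mix + ll)
        loglik_by_time[t] = total - prev_total
        prev_total = total

    return KalmanResult(
        filtered_mean=filtered_mean,
        filtered_var=filtered_var,
        log_likelihood=float(prev_total),
        loglik_by_time=loglik_by_time,
    )
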