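"""Seeded generators emulating the macro-level study data.

The real analysis runs on T = 28 annual national aggregates (1990-2017):
five collinear, integrated risk-factor prevalences driven by two correlated
latent factors; slowly varying covariates (disease prevalence, disability
weights, health-service supply, GDP per capita); and three noisy indicators
of a latent burden index.  Everything here reproduces that statistical
structure with known ground truth so each downstream stage can be tested
without any download.  All randomness flows through a single integer seed
and regeneration is bit-identical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .ssm_core import (
    CovariateSet,
    LatentTrajectory,
    SSMDataset,
    SSMParameters,
    measure,
    transition,
)

__all__ = [
    "RISK_FACTOR_NAMES",
    "DEFAULT_TRUE_PARAMS",
    "SyntheticConfig",
    "RiskFactorPanel",
    "simulate_risk_factor_panel",
    "simulate_covariates",
    "simulate_ssm_dataset",
    "apply_missingness",
    "simulate_study",
    "write_dataset_csv",
    "read_dataset_csv",
]

RISK_FACTOR_NAMES = (
    "obesity",
    "tobacco",
    "blood_glucose",
    "raised_blood_pressure",
    "cholesterol",
)


def _default_true_params() -> SSMParameters:
    """Reference ground truth for recovery studies.

    Drawn once from the inference prior supports, with the two utilization
    loadings (theta2, theta5) negative and of magnitude >= 0.3 so that
    sign-recovery checks are non-vacuous; magnitudes are comparable to
    typical single-disease estimates on the standardized scale.
    """
    return SSMParameters(
        alpha=np.array([0.5, 0.45, 0.35, 0.6, 0.4]),
        theta=np.array([0.7, -0.5, 0.6, 0.45, -0.55, 0.65, 0.35]),
        sigma_s2=0.3,
        sigma_m2=np.array([0.2, 0.25, 0.2]),
    )


DEFAULT_TRUE_PARAMS = _default_true_params()


@dataclass
class SyntheticConfig:
    """Study conditions for the generators.

    Defaults mirror the study setting: T = 28 annual points, two latent
    risk-factor drivers with correlation 0.35, integration orders
    (2, 1, 2, 1, 2) for (obesity, tobacco, blood glucose, raised blood
    pressure, cholesterol), and indicator missingness well below the 40%
    single-imputation threshold.
    """

    T: int = 28
    seed: int = 0
    factor_correlation: float = 0.35
    integration_orders: tuple[int, ...] = (2, 1, 2, 1, 2)
    missing_fraction_indicators: float = 0.15
    trend_slopes: tuple[float, ...] = (0.5, 0.3, 0.45, 0.35, 0.4)
    true_params: SSMParameters = field(default_factory=_default_true_params)
    factor_ar: float = 0.5
    factor_scale: float = 1.0
    #: idiosyncratic noise sd of the risk-factor series.  0.3 puts the
    #: standardized communalities near 0.9, matching the smooth, strongly
    #: collinear national prevalence series the generator emulates.
    noise_sd: float = 0.3
    start_year: int = 1990

    def __post_init__(self) -> None:
        if self.T < 10:
            raise ValueError(f"T must be >= 10, got {self.T}")
        if not -1.0 < self.factor_correlation < 1.0:
            raise ValueError("factor_correlation must lie in (-1, 1)")
        if len(self.integration_orders) != 5 or any(
            d not in (0, 1, 2) for d in self.integration_orders
        ):
            raise ValueError("integration_orders must be 5 integers in {0,1,2}")
        if not 0.0 <= self.missing_fraction_indicators < 0.4:
            raise ValueError(
                "missing_fraction_indicators must lie in [0, 0.4): above 40% "
                "missingness the single-imputation strategy is not defensible"
            )
        if len(self.trend_slopes) != 5:
            raise ValueError("trend_slopes must have 5 entries")

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.start_year, self.start_year + self.T)


@dataclass
class RiskFactorPanel:
    """Five named annual risk-factor series plus generation-time truth."""

    years: np.ndarray
    values: pd.DataFrame
    missing_mask: np.ndarray
    true_factors: np.ndarray  # (T, 2) stationary latent drivers
    true_loadings: np.ndarray  # (5, 2)

    def __post_init__(self) -> None:
        T = len(self.years)
        if len(self.values) != T or self.missing_mask.shape != (T, 5):
            raise ValueError("panel series lengths must equal len(years)")
        if np.any((~np.isnan(self.values.to_numpy())) & self.missing_mask):
            raise ValueError("missing_mask must be False wherever values are present")
        if np.any(np.all(self.true_loadings == 0, axis=1)):
            raise ValueError("each loading row needs at least one nonzero entry")


# Loadings of the five risk factors on the two latent drivers: a simple
# two-block structure (metabolic vs behavioral/pressure) with mild crossover.
_TRUE_LOADINGS = np.array(
    [
        [0.80, 0.10],   # obesity
        [0.05, 0.75],   # tobacco
        [0.75, 0.05],   # blood glucose
        [0.10, 0.80],   # raised blood pressure
        [0.70, 0.15],   # cholesterol
    ]
)


def _stationary_factors(config: SyntheticConfig, rng: np.random.Generator) -> np.ndarray:
    """Bivariate AR(1) factors with the configured cross-correlation."""
    rho = config.factor_correlation
    phi = config.factor_ar
    chol = np.linalg.cholesky(np.array([[1.0, rho], [rho, 1.0]]))
    innov = rng.standard_normal((config.T, 2)) @ chol.T * np.sqrt(1 - phi**2)
    eta = np.zeros((config.T, 2))
    eta[0] = rng.standard_normal(2) @ chol.T
    for t in range(1, config.T):
        eta[t] = phi * eta[t - 1] + innov[t]
    return config.factor_scale * eta


def simulate_risk_factor_panel(config: SyntheticConfig) -> RiskFactorPanel:
    """Integrated, trending risk-factor series driven by two latent factors.

    Each series is the d-fold cumulative sum of a stationary two-factor-plus-
    noise process (d = the series' integration order) plus a linear trend.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 11]))
    eta = _stationary_factors(config, rng)
    base = eta @ _TRUE_LOADINGS.T + config.noise_sd * rng.standard_normal((config.T, 5))
    t_idx = np.arange(config.T, dtype=float)
    series = np.empty((config.T, 5))
    for i, d in enumerate(config.integration_orders):
        s = base[:, i]
        for _ in range(d):
            s = np.cumsum(s)
        series[:, i] = s + config.trend_slopes[i] * t_idx
    values = pd.DataFrame(series, columns=list(RISK_FACTOR_NAMES))
    return RiskFactorPanel(
        years=config.years,
        values=values,
        missing_mask=np.zeros((config.T, 5), dtype=bool),
        true_factors=eta,
        true_loadings=_TRUE_LOADINGS.copy(),
    )


def _trend_ar1(rng, T, start, slope, ar=0.7, innov_sd=0.3):
    noise = np.zeros(T)
    noise[0] = rng.normal(0, innov_sd)
    eps = rng.normal(0, innov_sd, T)
    for t in range(1, T):
        noise[t] = ar * noise[t - 1] + eps[t]
    return start + slope * np.arange(T) + noise


def simulate_covariates(
    config: SyntheticConfig, missing_blocks: bool = False
) -> CovariateSet:
    """Smooth trending covariates on natural scales.

    Produces disease prevalence (u2, cases per 100k), mild/moderate and
    severe disability-weight averages (u3, u4, proportions in (0,1)), beds
    and specialists per 10k (z1, z2) and a GDP-per-capita analogue (z3).
    ``missing_blocks`` injects a contiguous missing run into z1 and z2 only,
    matching the supply series that were incomplete in the study.  u1 is left
    as NaN here: in the pipeline it is the risk-factor factor score.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 13]))
    T = config.T
    u2 = _trend_ar1(rng, T, start=900.0, slope=18.0, innov_sd=25.0)
    # disability weights: logistic of a drifting latent keeps them in (0,1)
    u3 = 1.0 / (1.0 + np.exp(-_trend_ar1(rng, T, -1.6, 0.012, innov_sd=0.05)))
    u4 = 1.0 / (1.0 + np.exp(-_trend_ar1(rng, T, -0.4, 0.010, innov_sd=0.05)))
    z1 = _trend_ar1(rng, T, start=14.0, slope=0.15, innov_sd=0.35)
    z2 = _trend_ar1(rng, T, start=8.0, slope=0.20, innov_sd=0.30)
    z3 = _trend_ar1(rng, T, start=1200.0, slope=65.0, innov_sd=55.0)
    if missing_blocks:
        frac = max(config.missing_fraction_indicators, 0.1)
        block = max(2, int(round(frac * T)))
        for z in (z1, z2):
            start = int(rng.integers(0, T - block + 1))
            z[start : start + block] = np.nan
    u1 = np.full(T, np.nan)
    return CovariateSet(u1=u1, u2=u2, u3=u3, u4=u4, z1=z1, z2=z2, z3=z3)


def simulate_ssm_dataset(
    params: SSMParameters,
    covariates: CovariateSet,
    factor_scores: np.ndarray,
    config: SyntheticConfig,
    x_init: float | None = None,
) -> tuple[SSMDataset, LatentTrajectory]:
    """Generate the latent burden path and its three noisy indicators.

    The state starts at ``x_init`` if given, otherwise at a U(-3,3) draw, and
    evolves from t = 2 with Gaussian noise of variance ``sigma_s2``; the
    indicators are produced by the three measurement equations with their
    respective variances.  The true latent trajectory is returned alongside
    for recovery tests.  Covariates should already be on the scale the model
    is meant to run on (standardized, in the pipeline).
    """
    T = config.T
    factor_scores = np.asarray(factor_scores, dtype=float)
    if len(factor_scores) != T or len(covariates) != T:
        raise ValueError("factor_scores and covariates must have length T")
    cov = CovariateSet(
        u1=factor_scores,
        u2=covariates.u2,
        u3=covariates.u3,
        u4=covariates.u4,
        z1=covariates.z1,
        z2=covariates.z2,
        z3=covariates.z3,
    )
    if not cov.is_complete():
        raise ValueError("covariates must be complete before simulating the SSM")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 17]))
    U = cov.state_covariates()
    Z = cov.measurement_covariates()
    x = np.empty(T)
    x[0] = rng.uniform(-3.0, 3.0) if x_init is None else float(x_init)
    state_sd = np.sqrt(params.sigma_s2)
    for t in range(1, T):
        x[t] = transition(x[t - 1], U[t], params, noise=state_sd * rng.standard_normal())
    meas_sd = np.sqrt(params.sigma_m2)
    noises = rng.standard_normal((T, 3)) * meas_sd
    y1, y2, y3 = measure(x, Z, params, noises)
    dataset = SSMDataset(years=config.years, covariates=cov, y1=y1, y2=y2, y3=y3)
    return dataset, LatentTrajectory(x=x)


def apply_missingness(dataset: SSMDataset, fraction: float, seed: int) -> SSMDataset:
    """MCAR-mask the two utilization indicators (y2, y3); y1 stays complete.

    Only the health-service utilization series had missing observations in
    the study, so the mask never touches y1.
    """
    if not 0.0 <= fraction < 0.4:
        raise ValueError(
            "missing fraction must lie in [0, 0.4); the mean-imputation "
            "strategy is only justified below 40% missingness"
        )
    if fraction == 0.0:
        return dataset
    rng = np.random.default_rng(np.random.SeedSequence([seed, 19]))
    T = len(dataset)
    y2 = dataset.y2.copy()
    y3 = dataset.y3.copy()
    y2[rng.random(T) < fraction] = np.nan
    y3[rng.random(T) < fraction] = np.nan
    return SSMDataset(
        years=dataset.years, covariates=dataset.covariates, y1=dataset.y1, y2=y2, y3=y3
    )


def _standardize(a: np.ndarray) -> np.ndarray:
    return (a - np.nanmean(a)) / np.nanstd(a, ddof=1)


def simulate_study(
    config: SyntheticConfig,
    missing_indicators: bool = False,
    missing_covariates: bool = False,
) -> tuple[SSMDataset, LatentTrajectory, RiskFactorPanel]:
    """One full synthetic study on the standardized model scale.

    The state-equation risk-factor covariate u1 is the standardized first
    integrated latent factor (what a factor-score estimate targets); the
    remaining covariates are standardized before simulation so the generated
    indicators live on the scale inference operates on.
    """
    panel = simulate_risk_factor_panel(config)
    u1 = _standardize(np.cumsum(panel.true_factors[:, 0]))
    raw = simulate_covariates(config, missing_blocks=False)
    cov = CovariateSet(
        u1=u1,
        u2=_standardize(raw.u2),
        u3=_standardize(raw.u3),
        u4=_standardize(raw.u4),
        z1=_standardize(raw.z1),
        z2=_standardize(raw.z2),
        z3=_standardize(raw.z3),
    )
    dataset, latent = simulate_ssm_dataset(config.true_params, cov, u1, config)
    if missing_indicators and config.missing_fraction_indicators > 0:
        dataset = apply_missingness(
            dataset, config.missing_fraction_indicators, config.seed
        )
    if missing_covariates:
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 23]))
        block = max(2, int(round(0.15 * config.T)))
        for name in ("z1", "z2"):
            z = getattr(dataset.covariates, name).copy()
            start = int(rng.integers(1, config.T - block))
            z[start : start + block] = np.nan
            setattr(dataset.covariates, name, z)
    return dataset, latent, panel


_CSV_COLUMNS = ("u1", "u2", "u3", "u4", "z1", "z2", "z3", "y1", "y2", "y3")


def write_dataset_csv(dataset: SSMDataset, path, sidecar: dict | None = None) -> None:
    """Write the wide exchange CSV (empty cell = missing) + JSON sidecar."""
    path = Path(path)
    df = pd.DataFrame({"year": dataset.years})
    cov = dataset.covariates
    for name in _CSV_COLUMNS[:7]:
        df[name] = getattr(cov, name)
    df["y1"], df["y2"], df["y3"] = dataset.y1, dataset.y2, dataset.y3
    df.to_csv(path, index=False)
    if sidecar is not None:
        with open(path.with_suffix(".json"), "w") as fh:
            json.dump(sidecar, fh, indent=2)


def read_dataset_csv(path) -> SSMDataset:
    df = pd.read_csv(path)
    missing = [c for c in ("year",) + _CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"dataset CSV is missing required columns: {missing}")
    cov = CovariateSet(**{n: df[n].to_numpy(float) for n in _CSV_COLUMNS[:7]})
    return SSMDataset(
        years=df["year"].to_numpy(),
        covariates=cov,
        y1=df["y1"].to_numpy(float),
        y2=df["y2"].to_numpy(float),
        y3=df["y3"].to_numpy(float),
    )
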