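"""Trend testing, stationarity testing, imputation and standardization.

Upstream of the state-space fit the study data need: (i) monotonic-trend
detection (Mann-Kendall, and a sieve-bootstrap t-test that respects serial
dependence), (ii) integration-order determination via the augmented
Dickey-Fuller test, and (iii) missing-data handling - linear interpolation
for trend checking, mean imputation for the supply covariates in the online
filter path, and EM-with-bootstrapping (EMB) multiple imputation for the
utilization indicators in the PIMH path.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.tsa.stattools import adfuller

__all__ = [
    "TrendTestResult",
    "StationarityResult",
    "ImputationSet",
    "mann_kendall_test",
    "sieve_bootstrap_trend_test",
    "adf_test",
    "integration_order",
    "linear_interpolate",
    "mean_impute",
    "emb_multiple_impute",
    "standardize",
]


class TrendMethod(str, Enum):
    mann_kendall = "mann_kendall"
    sieve_bootstrap_t = "sieve_bootstrap_t"


@dataclass
class TrendTestResult:
    statistic: float
    p_value: float
    method: TrendMethod
    n_boot: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p_value outside [0, 1]")


@dataclass
class StationarityResult:
    adf_statistic: float
    p_value: float
    lag_order: int
    regression_terms: str = "constant+trend"

    def __post_init__(self) -> None:
        if self.lag_order < 0:
            raise ValueError("lag order must be >= 0")


@dataclass
class ImputationSet:
    """m completed copies of a panel plus the EM-estimated MVN moments."""

    panels: list[pd.DataFrame]
    m: int
    em_means: np.ndarray
    em_covariance: np.ndarray
    converged: list[bool]

    def __post_init__(self) -> None:
        if self.m < 1 or len(self.panels) != self.m:
            raise ValueError("ImputationSet requires m >= 1 matching panels")


def mann_kendall_test(series) -> TrendTestResult:
    """Two-sided Mann-Kendall monotonic-trend test.

    S = sum over pairs i<j of sign(x_j - x_i); the normal approximation uses
    the tie-corrected variance and a continuity correction.  Missing entries
    are dropped (pairs are formed over observed values only).
    """
    x = np.asarray(series, dtype=float)
    x = x[~np.isnan(x)]
    n = len(x)
    if n < 4:
        raise ValueError("Mann-Kendall test requires at least 4 observed points")
    s = int(np.sum(np.sign(x[None, :] - x[:, None])[np.triu_indices(n, k=1)]))
    _, counts = np.unique(x, return_counts=True)
    ties = counts[counts > 1]
    var_s = (n * (n - 1) * (2 * n + 5) - np.sum(ties * (ties - 1) * (2 * ties + 5))) / 18.0
    if var_s == 0:
        return TrendTestResult(0.0, 1.0, TrendMethod.mann_kendall)
    if s > 0:
        z = (s - 1) / np.sqrt(var_s)
    elif s < 0:
        z = (s + 1) / np.sqrt(var_s)
    else:
        z = 0.0
    p = 2.0 * stats.norm.sf(abs(z))
    return TrendTestResult(float(s), float(min(p, 1.0)), TrendMethod.mann_kendall)


def _ols_trend_t(x: np.ndarray) -> float:
    """t-statistic for the slope of x_t = a + b t (vectorized over columns)."""
    n = x.shape[0]
    t = np.arange(n, dtype=float)
    tc = t - t.mean()
    xc = x - x.mean(axis=0)
    stt = float(tc @ tc)
    b = tc @ xc / stt
    resid = xc - np.outer(tc, b) if x.ndim > 1 else xc - tc * b
    dof = n - 2
    s2 = np.sum(resid**2, axis=0) / dof
    se = np.sqrt(s2 / stt)
    return b / se


def _fit_ar_sieve(resid: np.ndarray, max_p: int) -> tuple[np.ndarray, np.ndarray]:
    """AR(p) sieve for the bootstrap: order by BIC, innovations df-corrected.

    Candidate orders are compared on a common conditioning sample (the last
    n - max_p points) so the information criteria are commensurable; the
    selected order is then refitted on the full sample.  BIC is used because
    plain AIC over-selects spurious lags on short independent series, which
    makes the bootstrap trend test anti-conservative.  The innovations are
    inflated for the degrees of freedom absorbed by the trend and AR fits.
    """
    n = len(resid)
    max_p = int(min(max_p, max(n - 10, 1)))
    m = n - max_p
    best_p, best_ic = 0, np.inf
    for p in range(max_p + 1):
        Y = resid[max_p:]
        if p == 0:
            e = Y - Y.mean()
            k = 1
        else:
            X = np.column_stack(
                [np.ones(m)] + [resid[max_p - j : n - j] for j in range(1, p + 1)]
            )
            coef, _, _, _ = np.linalg.lstsq(X, Y, rcond=None)
            e = Y - X @ coef
            k = p + 1
        sigma2 = float(e @ e) / m
        if sigma2 <= 0:
            continue
        ic = m * np.log(sigma2) + k * np.log(m)
        if ic < best_ic:
            best_ic, best_p = ic, p
    p = best_p
    if p == 0:
        e = resid - resid.mean()
        coefs = np.empty(0)
        dof = n - 1
    else:
        Y = resid[p:]
        X = np.column_stack(
            [np.ones(n - p)] + [resid[p - j : n - j] for j in range(1, p + 1)]
        )
        coef, _, _, _ = np.linalg.lstsq(X, Y, rcond=None)
        e = Y - X @ coef
        coefs = coef[1:]
        dof = len(Y) - (p + 1)
    e = e - e.mean()
    e = e * np.sqrt(len(e) / max(dof - 2, 1))
    return coefs, e


def sieve_bootstrap_trend_test(
    series, n_boot: int = 1000, seed: int = 0
) -> TrendTestResult:
    """Linear-trend t-test with an AR-sieve bootstrap null distribution.

    The observed statistic is the OLS slope t-statistic; an AR(p) sieve
    (order by BIC, capped at n/4) is fitted to the detrended residuals, and
    bootstrap series are rebuilt under H0 (zero slope) by resampling the AR
    innovations.  The p-value is the proportion of |t*| >= |t_obs|.  The
    whole procedure is invariant to affine rescaling of the input.
    """
    x = np.asarray(series, dtype=float)
    if np.isnan(x).any():
        raise ValueError("sieve bootstrap test requires a complete series")
    n = len(x)
    if n < 8:
        raise ValueError("sieve bootstrap trend test requires length >= 8")
    if n_boot < 99:
        raise ValueError("n_boot must be >= 99")
    t_obs = float(_ols_trend_t(x))
    # detrend, fit the sieve
    t = np.arange(n, dtype=float)
    slope, intercept = np.polyfit(t, x, 1)
    resid = x - (intercept + slope * t)
    max_p = max(1, n // 4)
    coefs, innov = _fit_ar_sieve(resid, max_p)
    p = len(coefs)
    burn = 20  # spin-up so bootstrap series start from the AR stationary law
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(innov), size=(n_boot, n + p + burn))
    e_star = innov[idx]
    # regenerate AR residual series under H0, vectorized over replicates
    r = np.zeros((n_boot, n + p + burn))
    for tt in range(p, n + p + burn):
        acc = e_star[:, tt].copy()
        for k in range(1, p + 1):
            acc += coefs[k - 1] * r[:, tt - k]
        r[:, tt] = acc
    x_star = x.mean() + r[:, p + burn :]  # H0: no trend
    t_star = _ols_trend_t(x_star.T)
    p_val = float(np.mean(np.abs(t_star) >= abs(t_obs)))
    return TrendTestResult(t_obs, p_val, TrendMethod.sieve_bootstrap_t, n_boot=n_boot)


def adf_test(series, max_lag: int | None = None) -> StationarityResult:
    """Augmented Dickey-Fuller unit-root test with constant + trend terms.

    Regresses the first difference on a constant, a deterministic trend, the
    lagged level and AIC-selected lagged differences; the null is a unit
    root.  P-values come from statsmodels' MacKinnon response surface.
    """
    x = np.asarray(series, dtype=float)
    x = x[~np.isnan(x)]
    if np.ptp(x) == 0:
        raise ValueError("ADF test is degenerate for a constant series")
    if max_lag is not None and len(x) <= max_lag + 3:
        raise ValueError("series too short for the requested max_lag")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        stat, p, usedlag, _, _, _ = adfuller(
            x, maxlag=max_lag, regression="ct", autolag="AIC"
        )
    return StationarityResult(float(stat), float(p), int(usedlag))


def integration_order(series, max_d: int = 2, alpha: float = 0.05) -> int:
    """Smallest d <= max_d whose d-th difference rejects the ADF null.

    Returns ``max_d + 1`` when even the max_d-th difference fails to reject
    (series more persistent than the allowed differencing).
    """
    if max_d > 2:
        raise ValueError("max_d above 2 is not supported")
    x = np.asarray(series, dtype=float)
    for d in range(max_d + 1):
        if adf_test(x).p_value < alpha:
            return d
        x = np.diff(x)
    return max_d + 1


def linear_interpolate(series) -> np.ndarray:
    """Fill interior gaps linearly; extend endpoints by the nearest value."""
    x = np.asarray(series, dtype=float)
    obs = ~np.isnan(x)
    if obs.sum() < 2:
        raise ValueError("linear interpolation requires at least 2 observed points")
    idx = np.arange(len(x), dtype=float)
    return np.interp(idx, idx[obs], x[obs])


def mean_impute(series) -> np.ndarray:
    """Replace missing cells with the observed mean (valid below 40% missing)."""
    x = np.asarray(series, dtype=float)
    miss = np.isnan(x)
    if miss.mean() >= 0.4:
        raise ValueError(
            "mean imputation requires missingness below the 40% threshold"
        )
    if miss.all() or len(x) == 0:
        raise ValueError("mean imputation needs at least one observed value")
    out = x.copy()
    out[miss] = np.nanmean(x)
    return out


def _em_mvn(
    data: np.ndarray, max_iter: int, tol: float, ridge: float = 1e-8
) -> tuple[np.ndarray, np.ndarray, bool]:
    """EM for the MVN mean/covariance with missing cells.

    E-step computes conditional expectations (and covariances) of missing
    blocks given observed cells; M-step updates (mu, Sigma).  A near-singular
    Sigma is ridge-regularized.
    """
    n, p = data.shape
    miss = np.isnan(data)
    filled = data.copy()
    col_means = np.nanmean(data, axis=0)
    inds = np.where(miss)
    filled[inds] = np.take(col_means, inds[1])
    mu = filled.mean(axis=0)
    sigma = np.cov(filled, rowvar=False, ddof=0) + ridge * np.eye(p)
    patterns: dict[bytes, np.ndarray] = {}
    for i in range(n):
        patterns.setdefault(miss[i].tobytes(), []).append(i)  # type: ignore[arg-type]
    converged = False
    for _ in range(max_iter):
        ex = filled.copy()
        extra_cov = np.zeros((p, p))
        for key, rows in patterns.items():
            mpat = np.frombuffer(key, dtype=bool)
            if not mpat.any():
                continue
            o = ~mpat
            rows = np.asarray(rows)
            soo = sigma[np.ix_(o, o)]
            smo = sigma[np.ix_(mpat, o)]
            try:
                w = np.linalg.solve(soo, smo.T).T
            except np.linalg.LinAlgError:
                soo = soo + ridge * np.eye(o.sum())
                w = np.linalg.solve(soo, smo.T).T
            cond_mean = mu[mpat] + (data[np.ix_(rows, o)] - mu[o]) @ w.T
            ex[np.ix_(rows, mpat)] = cond_mean
            cond_cov = sigma[np.ix_(mpat, mpat)] - w @ smo.T
            extra_cov[np.ix_(mpat, mpat)] += len(rows) * cond_cov
        mu_new = ex.mean(axis=0)
        centered = ex - mu_new
        sigma_new = (centered.T @ centered + extra_cov) / n
        delta = np.max(np.abs(mu_new - mu)) + np.max(np.abs(sigma_new - sigma))
        mu, sigma, filled = mu_new, sigma_new, ex
        if delta < tol:
            converged = True
            break
    if np.linalg.cond(sigma) > 1e10:
        sigma = sigma + 1e-6 * np.eye(p)
    return mu, sigma, converged


def emb_multiple_impute(
    panel: pd.DataFrame,
    m: int = 5,
    seed: int = 0,
    max_iter: int = 200,
    tol: float = 1e-6,
) -> ImputationSet:
    """EM-with-bootstrapping multiple imputation under an MVN model.

    For each of m nonparametric bootstrap resamples of the rows, EM estimates
    the MVN (mu, Sigma); the original missing cells are then filled with
    draws from their conditional normal given the row's observed cells under
    that resample's parameters.  Observed cells are never altered; the m
    completed panels carry the between-imputation uncertainty.  Degenerate
    resamples (a column with < 2 observed values) are redrawn.
    """
    if panel.shape[1] < 2:
        raise ValueError("EMB imputation needs at least 2 columns")
    data = panel.to_numpy(dtype=float)
    n, p = data.shape
    miss = np.isnan(data)
    if np.any((~miss).sum(axis=0) < 2):
        raise ValueError("each column needs at least 2 observed values")
    mu_full, sigma_full, _ = _em_mvn(data, max_iter, tol)
    if not miss.any():
        panels = [panel.copy() for _ in range(m)]
        return ImputationSet(panels, m, mu_full, sigma_full, [True] * m)
    rng = np.random.default_rng(seed)
    panels = []
    converged_flags = []
    for _ in range(m):
        for _attempt in range(100):
            rows = rng.integers(0, n, size=n)
            boot = data[rows]
            if np.all((~np.isnan(boot)).sum(axis=0) >= 2):
                break
        else:
            raise RuntimeError("could not draw a non-degenerate bootstrap resample")
        mu_b, sigma_b, conv = _em_mvn(boot, max_iter, tol)
        if not conv:
            warnings.warn("EM did not converge on a bootstrap resample", RuntimeWarning)
        completed = data.copy()
        for i in range(n):
            mpat = miss[i]
            if not mpat.any():
                continue
            o = ~mpat
            if o.any():
                soo = sigma_b[np.ix_(o, o)]
                smo = sigma_b[np.ix_(mpat, o)]
                w = np.linalg.solve(soo, smo.T).T
                cmean = mu_b[mpat] + w @ (data[i, o] - mu_b[o])
                ccov = sigma_b[np.ix_(mpat, mpat)] - w @ smo.T
            else:
                cmean = mu_b[mpat]
                ccov = sigma_b[np.ix_(mpat, mpat)]
            ccov = (ccov + ccov.T) / 2
            jitter = 1e-10 * np.eye(mpat.sum())
            completed[i, mpat] = rng.multivariate_normal(
                cmean, ccov + jitter, method="eigh"
            )
        panels.append(pd.DataFrame(completed, columns=panel.columns, index=panel.index))
        converged_flags.append(conv)
    return ImputationSet(panels, m, mu_full, sigma_full, converged_flags)


def standardize(panel: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Scale each series to observed-cell mean 0 / sd 1; return the transform.

    The second return value has one row per series with columns ``mean`` and
    ``sd`` so the transform can be inverted (x = z * sd + mean).
    """
    means = panel.mean(skipna=True)
    sds = panel.std(skipna=True, ddof=1)
    if (sds == 0).any() or sds.isna().any():
        bad = list(sds.index[(sds == 0) | sds.isna()])
        raise ValueError(f"cannot standardize constant series: {bad}")
    out = (panel - means) / sds
    params = pd.DataFrame({"mean": means, "sd": sds})
    return out, params
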