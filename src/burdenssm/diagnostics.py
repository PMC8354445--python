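"""Chain and filter quality checks.

Covers the convergence diagnostics applied to the PIMH chains
(autocorrelation, effective sample size, the Geweke early-vs-late mean
comparison) and the filter-quality table of root-mean-square discrepancy
between observed and one-pass-predicted indicators as a function of the
particle count.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .particle_filter import pf_likelihood
from .ssm_core import SSMDataset, SSMParameters, _measurement_terms

__all__ = [
    "DiagnosticsReport",
    "autocorrelation",
    "effective_sample_size",
    "geweke_test",
    "rmsd_by_particles",
    "chain_report",
    "plot_trace_acf",
]


@dataclass
class DiagnosticsReport:
    ess: dict[str, float]
    autocorrelation: dict[str, np.ndarray]
    geweke_z: dict[str, float]
    geweke_p: dict[str, float]


def autocorrelation(values, max_lag: int = 20) -> np.ndarray:
    """Sample autocorrelation at lags 1..max_lag (biased/ML normalization).

    A constant chain has undefined autocorrelation; it is reported as zeros
    with a warning rather than an error.
    """
    x = np.asarray(values, dtype=float)
    n = len(x)
    if n <= max_lag:
        raise ValueError("chain shorter than max_lag")
    xc = x - x.mean()
    denom = float(xc @ xc)
    if denom == 0.0:
        warnings.warn("constant chain: autocorrelation undefined, returning 0",
                      RuntimeWarning)
        return np.zeros(max_lag)
    return np.array([float(xc[k:] @ xc[:-k]) / denom for k in range(1, max_lag + 1)])


def effective_sample_size(values) -> float:
    """n / (1 + 2 * sum rho(k)) with initial-positive-sequence truncation.

    The autocorrelation sum runs while rho stays positive (Geyer's initial
    positive sequence, simplified to single lags) and the result is capped
    at n.
    """
    x = np.asarray(values, dtype=float)
    n = len(x)
    if n < 10:
        raise ValueError("need at least 10 draws for an ESS estimate")
    max_lag = min(n - 1, 1000)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        rho = autocorrelation(x, max_lag=max_lag)
    acc = 0.0
    for r in rho:
        if r <= 0.0:
            break
        acc += r
    return float(min(n, n / (1.0 + 2.0 * acc)))


def _batch_means_var(seg: np.ndarray, n_batches: int = 20) -> tuple[float, int]:
    """Variance of the segment mean by batch means; returns (var, df)."""
    n = len(seg)
    size = n // n_batches
    if size < 1:
        raise ValueError("segment too short for batch-means variance")
    trimmed = seg[: size * n_batches].reshape(n_batches, size)
    bm = trimmed.mean(axis=1)
    return float(bm.var(ddof=1) / n_batches), n_batches - 1


def geweke_test(
    values, first_frac: float = 0.1, last_frac: float = 0.5
) -> tuple[float, float]:
    """Early-vs-late mean comparison (default first 10% vs last 50%).

    z = (mean_first - mean_last) / sqrt(var_first + var_last) with the
    segment-mean variances estimated by batch means (20 batches).  The
    two-sided p-value uses a Student-t reference with Welch-Satterthwaite
    degrees of freedom - a small-sample correction for the handful of
    batches behind each variance estimate.
    """
    x = np.asarray(values, dtype=float)
    n = len(x)
    n1 = int(np.floor(first_frac * n))
    n2 = int(np.floor(last_frac * n))
    if n1 < 10 or n2 < 10:
        raise ValueError("both Geweke segments need at least 10 points")
    a, b = x[:n1], x[n - n2 :]
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("degenerate (constant) Geweke segment")
    v1, df1 = _batch_means_var(a)
    v2, df2 = _batch_means_var(b)
    z = (a.mean() - b.mean()) / np.sqrt(v1 + v2)
    df = (v1 + v2) ** 2 / (v1**2 / df1 + v2**2 / df2)
    p = 2.0 * stats.t.sf(abs(z), df)
    return float(z), float(p)


def chain_report(
    draws: pd.DataFrame, max_lag: int = 20
) -> DiagnosticsReport:
    """ESS, autocorrelation and Geweke diagnostics for each chain column."""
    ess, acf, gz, gp = {}, {}, {}, {}
    for col in draws.columns:
        vals = draws[col].to_numpy(dtype=float)
        ess[col] = effective_sample_size(vals)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            acf[col] = autocorrelation(vals, max_lag=max_lag)
        try:
            gz[col], gp[col] = geweke_test(vals)
        except ValueError:
            gz[col], gp[col] = np.nan, np.nan
    return DiagnosticsReport(ess=ess, autocorrelation=acf, geweke_z=gz, geweke_p=gp)


def rmsd_by_particles(
    dataset: SSMDataset,
    params: SSMParameters,
    particle_counts=(100, 500, 1000),
    replicates: int = 5,
    seed: int = 0,
) -> pd.DataFrame:
    """Root-mean-square discrepancy of each indicator vs the particle count.

    For each N, the filter runs at the given parameters, the indicators are
    predicted noise-free from the filtered state, and the RMSD over observed
    time points (t >= 2) is averaged across replicates.  One row per N, one
    column per indicator.
    """
    if any(n < 1 for n in particle_counts):
        raise ValueError("particle counts must be >= 1")
    y = dataset.indicators()
    obs = ~np.isnan(y)
    obs[:, 0] = False  # t = 1 carries no filtered information
    h, d, _ = _measurement_terms(dataset, params)
    ss = np.random.SeedSequence(seed)
    rows = []
    for N in particle_counts:
        acc = np.zeros(3)
        for child in ss.spawn(replicates):
            _, xhat = pf_likelihood(dataset, params, N=N, seed=child)
            pred = h[:, None] * xhat[None, :] + d
            for j in range(3):
                m = obs[j]
                acc[j] += np.sqrt(np.mean((y[j, m] - pred[j, m]) ** 2))
        rows.append(acc / replicates)
    return pd.DataFrame(rows, index=list(particle_counts), columns=["y1", "y2", "y3"])


def plot_trace_acf(draws: pd.DataFrame, path, max_lag: int = 20) -> None:
    """Optional trace + autocorrelation figure for a chain (one row per column)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    cols = list(draws.columns)
    fig, axes = plt.subplots(len(cols), 2, figsize=(9, 2.2 * len(cols)), squeeze=False)
    for i, col in enumerate(cols):
        vals = draws[col].to_numpy(dtype=float)
        axes[i][0].plot(vals, lw=0.5)
        axes[i][0].set_ylabel(col, fontsize=8)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            acf = autocorrelation(vals, max_lag=max_lag)
        axes[i][1].bar(np.arange(1, max_lag + 1), acf, width=0.6)
        axes[i][1].axhline(0.0, color="k", lw=0.5)
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
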