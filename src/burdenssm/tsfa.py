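"""Time-series factor analysis of the collinear risk-factor panel.

The five risk-factor prevalences are integrated and highly correlated, so
they are differenced to stationarity, a maximum-likelihood factor model is
fitted to the differenced (standardized) panel, the loadings are obliquely
rotated (quartimin) to allow correlated factors, and Bartlett factor scores

    eta_hat_t = (B' W^-1 B)^-1 B' W^-1 y_t

are then computed on the *undifferenced* panel so the score series keeps the
original number of time points.  The scores feed the state equation as the
risk-factor covariate u1.

ML extraction uses the classical profiled likelihood: minimize the
discrepancy over uniquenesses with the loadings concentrated out through the
eigendecomposition of the uniqueness-scaled correlation matrix; rotation is
delegated to statsmodels' gradient-projection rotation routines.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from statsmodels.multivariate.factor_rotation import rotate_factors

__all__ = [
    "FactorModelFit",
    "FactorScores",
    "difference",
    "fit_tsfa",
    "bartlett_scores",
    "tucker_congruence",
    "align_loadings",
]

_PSI_FLOOR = 0.005  # uniqueness lower bound; hitting it flags a Heywood case


@dataclass
class FactorModelFit:
    """ML factor solution on the differenced panel.

    ``loadings`` (p x k) and the diagonal ``uniqueness_covariance`` together
    reproduce the standardized correlation structure as
    B Phi B' + W; ``intercept`` is the differenced-model drift (series means
    of the differenced panel), ``factor_correlation`` the k x k inter-factor
    correlation after oblique rotation.
    """

    loadings: np.ndarray
    uniqueness_covariance: np.ndarray
    intercept: np.ndarray
    factor_correlation: np.ndarray
    rotation: str
    k: int
    differencing_order: int
    heywood: bool
    converged: bool
    columns: tuple[str, ...]

    def __post_init__(self) -> None:
        w = np.diag(self.uniqueness_covariance)
        if np.any(w <= 0):
            raise ValueError("uniqueness variances must be positive")
        phi = self.factor_correlation
        if not np.allclose(phi, phi.T) or not np.allclose(np.diag(phi), 1.0):
            raise ValueError("factor correlation must be symmetric with unit diagonal")

    def implied_correlation(self) -> np.ndarray:
        B, phi = self.loadings, self.factor_correlation
        return B @ phi @ B.T + self.uniqueness_covariance


@dataclass
class FactorScores:
    years: np.ndarray
    scores: np.ndarray  # (T, k)

    def __post_init__(self) -> None:
        if len(self.years) != len(self.scores):
            raise ValueError("scores length must match years")


def difference(panel: pd.DataFrame, d: int) -> pd.DataFrame:
    """d-fold first differences; output has T - d rows."""
    if d < 0:
        raise ValueError("differencing order must be >= 0")
    if d >= len(panel):
        raise ValueError(f"cannot take {d} differences of a length-{len(panel)} panel")
    out = panel.copy()
    for _ in range(d):
        out = out.diff().iloc[1:]
    return out


def _ml_extract(R: np.ndarray, k: int, n_starts: int = 4, seed: int = 0):
    """Profiled-ML extraction: optimize uniquenesses, loadings by eigen step."""
    p = R.shape[0]

    def discrepancy(logpsi: np.ndarray) -> float:
        psi = np.exp(logpsi)
        d = 1.0 / np.sqrt(psi)
        ev = np.linalg.eigvalsh(R * np.outer(d, d))[::-1][k:]
        ev = np.maximum(ev, 1e-12)
        return float(np.sum(ev - np.log(ev) - 1.0))

    rng = np.random.default_rng(seed)
    best = None
    for s in range(n_starts):
        start = np.full(p, 0.5) if s == 0 else rng.uniform(0.2, 0.9, p)
        res = minimize(
            discrepancy,
            np.log(start),
            method="L-BFGS-B",
            bounds=[(np.log(_PSI_FLOOR), 0.0)] * p,
        )
        if best is None or res.fun < best.fun:
            best = res
    psi = np.exp(best.x)
    d = 1.0 / np.sqrt(psi)
    ev, vec = np.linalg.eigh(R * np.outer(d, d))
    ev, vec = ev[::-1], vec[:, ::-1]
    load = vec[:, :k] * np.sqrt(np.maximum(ev[:k] - 1.0, 0.0))
    load = load / d[:, None]
    return load, psi, bool(best.success)


def _orient(loadings: np.ndarray, phi: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Sign convention: largest-|loading| entry of each factor positive."""
    signs = np.ones(loadings.shape[1])
    for j in range(loadings.shape[1]):
        i = np.argmax(np.abs(loadings[:, j]))
        if loadings[i, j] < 0:
            signs[j] = -1.0
    L = loadings * signs
    return L, signs[:, None] * phi * signs[None, :]


def fit_tsfa(
    differenced_panel: pd.DataFrame,
    k: int = 2,
    rotation: str = "quartimin",
    differencing_order: int = 2,
    seed: int = 0,
) -> FactorModelFit:
    """ML factor model on the differenced panel's correlation matrix.

    With ``rotation='quartimin'`` the solution is obliquely rotated and the
    inter-factor correlation reported; ``rotation='none'`` keeps the
    orthogonal ML solution.  Uniquenesses pinned at the lower bound are
    flagged as Heywood cases (a warning, not an error: on weak-structure
    data the boundary solution is the ML solution).
    """
    p = differenced_panel.shape[1]
    if k >= p:
        raise ValueError(f"k must be smaller than the number of series ({p})")
    X = differenced_panel.to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValueError("differenced panel must be complete")
    R = np.corrcoef(X, rowvar=False)
    load, psi, converged = _ml_extract(R, k, seed=seed)
    if not converged:
        raise RuntimeError("ML factor extraction failed to converge")
    heywood = bool(np.any(psi <= _PSI_FLOOR * 1.0001))
    if heywood:
        warnings.warn(
            "Heywood case: at least one uniqueness at its lower bound",
            RuntimeWarning,
        )
    if rotation == "quartimin" and k > 1:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            L, T = rotate_factors(load, "quartimin")
        phi = T.T @ T  # statsmodels convention: A = L T', so cov(T'f) = T'T
    elif rotation in ("none", "quartimin"):
        L, phi = load, np.eye(k)
        rotation = "none" if rotation == "none" else rotation
    else:
        raise ValueError(f"unknown rotation '{rotation}'")
    L, phi = _orient(L, phi)
    # scale scores by the standardization of the columns used for the fit
    return FactorModelFit(
        loadings=L,
        uniqueness_covariance=np.diag(psi),
        intercept=X.mean(axis=0),
        factor_correlation=phi,
        rotation=rotation,
        k=k,
        differencing_order=differencing_order,
        heywood=heywood,
        converged=converged,
        columns=tuple(differenced_panel.columns),
    )


def bartlett_scores(fit: FactorModelFit, undifferenced_panel: pd.DataFrame) -> FactorScores:
    """Weighted-least-squares factor scores on the undifferenced panel.

    Applies eta_hat_t = (B'W^-1 B)^-1 B'W^-1 y_t column-wise, with B and W
    taken from the differenced-data fit: the score series then has the full
    original length T.  The panel should be standardized like the fit input.
    """
    y = undifferenced_panel.to_numpy(dtype=float)
    B = fit.loadings
    if y.shape[1] != B.shape[0]:
        raise ValueError(
            f"panel width {y.shape[1]} does not match loading rows {B.shape[0]}"
        )
    w_inv = np.diag(1.0 / np.diag(fit.uniqueness_covariance))
    M = B.T @ w_inv @ B
    if np.linalg.cond(M) > 1e12:
        raise np.linalg.LinAlgError("B' W^-1 B is numerically singular")
    weights = np.linalg.solve(M, B.T @ w_inv)
    scores = y @ weights.T
    years = (
        undifferenced_panel.index.to_numpy()
        if undifferenced_panel.index.dtype.kind in "iu"
        else np.arange(len(y))
    )
    return FactorScores(years=years, scores=scores)


def tucker_congruence(a: np.ndarray, b: np.ndarray) -> float:
    """Tucker's congruence coefficient between two loading vectors."""
    return float(a @ b / np.sqrt((a @ a) * (b @ b)))


def align_loadings(estimated: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Permute and sign-flip estimated factors to best match the reference.

    Greedy assignment on |congruence|; returns the aligned loading matrix.
    Used by recovery tests where the factor order/sign is arbitrary.
    """
    k = reference.shape[1]
    cong = np.array(
        [
            [tucker_congruence(estimated[:, i], reference[:, j]) for j in range(k)]
            for i in range(k)
        ]
    )
    aligned = np.zeros_like(reference)
    used = set()
    for j in range(k):
        order = np.argsort(-np.abs(cong[:, j]))
        i = next(i for i in order if i not in used)
        used.add(i)
        aligned[:, j] = estimated[:, i] * np.sign(cong[i, j])
    return aligned
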