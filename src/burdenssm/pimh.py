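"""Particle Independent Metropolis-Hastings over the static parameters.

An independence sampler: candidate parameters are drawn from the uniform
prior supports (so proposal densities cancel in the acceptance ratio) and
the intractable marginal likelihood is replaced by the particle filter's
unbiased estimate - the pseudo-marginal construction, which leaves the exact
posterior invariant.  The current point's likelihood estimate is carried
over, never re-estimated, as pseudo-marginal validity requires.

Initialization follows the reference configuration: all coefficients start
at zero and all error variances at 0.01.  That point lies outside the prior
support (variances below 0.1), so the chain treats its log-prior as -inf and
the first in-support proposal is always accepted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .particle_filter import pf_likelihood
from .ssm_core import (
    PARAM_NAMES,
    PriorConfig,
    SSMDataset,
    SSMParameters,
    log_prior,
)

__all__ = [
    "MCMCChain",
    "PosteriorSummary",
    "propose",
    "acceptance_probability",
    "run_pimh",
    "run_pimh_multi_impute",
    "summarize",
]


@dataclass
class MCMCChain:
    """Parameter draws, likelihood estimates and the acceptance record."""

    draws: np.ndarray             # (n_iter, 16), rows ordered by PARAM_NAMES
    log_likelihoods: np.ndarray
    accepted: np.ndarray
    n_iter: int
    burn_in: int
    seed: int
    free: tuple[str, ...]
    state_trajectory: np.ndarray | None = None  # final PF run at posterior mean
    param_names: tuple[str, ...] = PARAM_NAMES

    def __post_init__(self) -> None:
        if len(self.draws) != self.n_iter:
            raise ValueError("len(draws) must equal n_iter")
        if not 0 <= self.burn_in < self.n_iter:
            raise ValueError("burn_in must lie in [0, n_iter)")

    @property
    def retained(self) -> np.ndarray:
        return self.draws[self.burn_in :]

    @property
    def acceptance_rate(self) -> float:
        return float(np.mean(self.accepted))

    def posterior_mean(self) -> SSMParameters:
        return SSMParameters.from_vector(self.retained.mean(axis=0))

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.draws, columns=list(self.param_names))
        df["log_likelihood"] = self.log_likelihoods
        df["accepted"] = self.accepted
        return df


@dataclass
class PosteriorSummary:
    """Per-parameter mean, sd and central 95% interval of retained draws."""

    table: pd.DataFrame  # index: parameter names; columns: mean, sd, q2.5, q97.5

    def __post_init__(self) -> None:
        if np.any(self.table["q2.5"] > self.table["q97.5"]):
            raise ValueError("quantile ordering violated (q2.5 > q97.5)")


def propose(
    prior: PriorConfig,
    rng: np.random.Generator,
    free: tuple[str, ...] = PARAM_NAMES,
    fixed: SSMParameters | None = None,
) -> SSMParameters:
    """Independent draw from the uniform proposal (= prior) supports.

    Coordinates not listed in ``free`` are copied from ``fixed``.
    """
    if fixed is None:
        vec = np.empty(len(PARAM_NAMES))
    else:
        vec = fixed.to_vector()
    for i, name in enumerate(PARAM_NAMES):
        if name in free:
            lo, hi = prior.bounds[name]
            vec[i] = rng.uniform(lo, hi)
    return SSMParameters.from_vector(vec)


def acceptance_probability(
    loglik_new: float,
    loglik_cur: float,
    logprior_new: float,
    logprior_cur: float,
) -> float:
    """min(1, exp((ll* + lp*) - (ll + lp))) with the proposal terms cancelled.

    An out-of-support proposal (logprior_new = -inf) is never accepted; an
    out-of-support *current* point (the reference initialization) makes any
    in-support proposal certain to be accepted.
    """
    if np.isneginf(logprior_new):
        return 0.0
    if np.isneginf(logprior_cur) or np.isneginf(loglik_cur):
        return 1.0
    log_ratio = (loglik_new + logprior_new) - (loglik_cur + logprior_cur)
    return float(min(1.0, np.exp(min(log_ratio, 0.0))))


def _initial_point(free: tuple[str, ...], fixed: SSMParameters | None) -> SSMParameters:
    vec = np.zeros(len(PARAM_NAMES)) if fixed is None else fixed.to_vector()
    for i, name in enumerate(PARAM_NAMES):
        if name in free:
            vec[i] = 0.01 if name.startswith("sigma") else 0.0
    return SSMParameters.from_vector(vec)


def run_pimh(
    dataset: SSMDataset,
    n_iter: int = 6250,
    burn_in: int = 1250,
    N: int = 1000,
    seed: int = 0,
    prior: PriorConfig | None = None,
    free: tuple[str, ...] = PARAM_NAMES,
    fixed: SSMParameters | None = None,
    likelihood_fn=None,
    final_pf: bool = True,
) -> MCMCChain:
    """Run the PIMH chain and a final filter pass at the posterior mean.

    Defaults reproduce the reference configuration: 6250 iterations of which
    the first 1250 are burn-in (5000 retained), N = 1000 particles.  Each
    iteration proposes from the uniform supports, estimates the likelihood
    with a fresh particle filter (per-iteration seeds spawned from the root
    seed) and applies the standard MH accept/reject rule.  ``free`` restricts
    sampling to a parameter subset with the rest held at ``fixed`` - used by
    oracle cross-checks on restricted sub-models.  ``likelihood_fn`` may
    replace the particle-filter estimate (signature
    ``fn(dataset, params, N, seed) -> (loglik, x_hat)``); substituting the
    exact Kalman likelihood turns the sampler into standard independence MH.
    """
    prior = prior or PriorConfig()
    if likelihood_fn is None:
        likelihood_fn = lambda ds, p, n, s: pf_likelihood(ds, p, N=n, seed=s, prior=prior)
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_iter + 2)
    rng = np.random.default_rng(children[0])

    draws = np.empty((n_iter, len(PARAM_NAMES)))
    logliks = np.empty(n_iter)
    accepted = np.zeros(n_iter, dtype=bool)

    current = _initial_point(free, fixed)
    cur_ll, _ = likelihood_fn(dataset, current, N, children[1])
    cur_lp = log_prior(current, prior, names=free)
    draws[0] = current.to_vector()
    logliks[0] = cur_ll

    for i in range(1, n_iter):
        cand = propose(prior, rng, free=free, fixed=fixed if fixed is not None else current)
        cand_ll, _ = likelihood_fn(dataset, cand, N, children[1 + i])
        cand_lp = log_prior(cand, prior, names=free)
        alpha = acceptance_probability(cand_ll, cur_ll, cand_lp, cur_lp)
        if rng.uniform() <= alpha:
            current, cur_ll, cur_lp = cand, cand_ll, cand_lp
            accepted[i] = True
        draws[i] = current.to_vector()
        logliks[i] = cur_ll

    chain = MCMCChain(
        draws=draws,
        log_likelihoods=logliks,
        accepted=accepted,
        n_iter=n_iter,
        burn_in=burn_in,
        seed=seed,
        free=tuple(free),
    )
    if final_pf:
        _, xhat = likelihood_fn(dataset, chain.posterior_mean(), N, children[1])
        chain.state_trajectory = xhat
    return chain


def summarize(chain: MCMCChain, free_only: bool = True) -> PosteriorSummary:
    """Posterior mean, sd and empirical 2.5%/97.5% quantiles of retained draws."""
    retained = chain.retained
    if len(retained) < 2:
        raise ValueError("need at least 2 retained draws to summarize")
    names = list(chain.param_names)
    cols = [names.index(n) for n in chain.free] if free_only else range(len(names))
    rows = {}
    for c in cols:
        vals = retained[:, c]
        rows[names[c]] = {
            "mean": float(vals.mean()),
            "sd": float(vals.std(ddof=1)),
            "q2.5": float(np.quantile(vals, 0.025)),
            "q97.5": float(np.quantile(vals, 0.975)),
        }
    return PosteriorSummary(table=pd.DataFrame(rows).T)


def run_pimh_multi_impute(
    datasets: list[SSMDataset],
    n_iter: int = 6250,
    burn_in: int = 1250,
    N: int = 1000,
    seed: int = 0,
    prior: PriorConfig | None = None,
    sub_seeds: list[int] | None = None,
    **kwargs,
) -> tuple[list[MCMCChain], PosteriorSummary]:
    """One PIMH chain per imputed panel; estimates pooled across panels.

    Each panel gets a distinct sub-seed (override with ``sub_seeds``).  The
    pooled summary averages the per-panel posterior means, sds and quantiles
    (the reference analysis reports the average over the five imputed
    samples); the per-panel chains are returned alongside.
    """
    if not datasets:
        raise ValueError("need at least one completed panel")
    if sub_seeds is None:
        sub_seeds = np.random.SeedSequence(seed).generate_state(len(datasets)) % (2**31)
    elif len(sub_seeds) != len(datasets):
        raise ValueError("sub_seeds length must match the number of panels")
    chains = [
        run_pimh(
            ds, n_iter=n_iter, burn_in=burn_in, N=N, seed=int(s), prior=prior, **kwargs
        )
        for ds, s in zip(datasets, sub_seeds)
    ]
    tables = [summarize(ch).table for ch in chains]
    pooled = sum(tables[1:], tables[0].copy()) / len(tables)
    return chains, PosteriorSummary(table=pooled)
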