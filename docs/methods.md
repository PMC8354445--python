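# Methods

## Model

A scalar latent burden index `x_t` per disease group evolves as an AR(1)
with exogenous drivers and is observed through three linear indicators
(see the README for the equations). All series are annual national
aggregates; the model operates on standardized series throughout, so every
coefficient is unitless and comparable across indicators. Noises are
Gaussian and mutually independent; the three indicators are conditionally
independent given the state, which is what lets the per-indicator weight
factors multiply.

Time indexing: the state recursion runs t = 2..T. The initial value x₁ is
a draw from U(−3, 3) and the observations at t = 1 contribute no likelihood
term — this mirrors the sequential filter, which starts weighting at t = 2
and reports x̂₁ as the unweighted mean of the initial particles. The exact
Kalman oracle adopts the same convention so that both methods target the
same marginal likelihood p(y₂..y_T | parameters).

Priors (also the PIMH proposal): uniform on each parameter's support —
(0,1) for α₁..α₅, θ₁, θ₃, θ₄, θ₆, θ₇; (−1,1) for the two utilization
loadings θ₂, θ₅ (the only coefficients allowed to be negative); (0.1, 1.5)
for all four noise variances.

## Estimation

**Particle filter (online).** Sequential importance resampling over the
joint vector [x, θ₁..θ₇, α₁..α₅, σ²'s]. Static parameters receive
artificial random-walk dynamics with N(0, 0.01) innovations each step;
jittered coordinates are reflected at their prior bounds, which keeps the
ensemble inside the support (variances in particular stay positive) without
piling probability mass on the boundary. Weights are computed in log space
and normalized by log-sum-exp; the per-step estimate is the
normalized-weight average; resampling is multinomial every step (systematic
resampling is available behind a flag but is not the default, since the
multinomial scheme matches the iid importance-sampling derivation of the
weights). A missing indicator cell contributes a likelihood factor of one:
a time step with no observations leaves the normalized weights at exactly
1/N and adds exactly zero to the log-likelihood.

**Likelihood estimate.** The fixed-parameter bootstrap filter returns
`Σ_t log( (1/N) Σ_i w_t^(i) )`, the standard unbiased estimator of the
marginal likelihood. Unbiasedness is verified against the exact Kalman
likelihood in the acceptance suite (mean of the likelihood ratio over 50
seeded runs within 3 Monte-Carlo SEs of one).

**PIMH.** Independence Metropolis-Hastings whose proposal equals the prior,
so proposal densities cancel and the acceptance ratio reduces to the
(estimated) likelihood ratio. The current point's likelihood estimate is
carried over, never recomputed — pseudo-marginal validity requires this.
Initialization follows the reference configuration (coefficients at zero,
variances at 0.01); that point lies outside the prior support, so its
log-prior is −∞ and the first in-support proposal is accepted with
probability one. The printed acceptance rule in the source algorithm
("accept if probability < U") is inverted relative to standard MH; the
standard rule (accept iff U ≤ α) is implemented, consistent with the
surrounding derivation. After the loop a final filter pass at the
posterior-mean parameters produces the reported trajectory.

**Multiple imputation.** In the PIMH path the incomplete panel is completed
m = 5 times by EMB (nonparametric bootstrap of rows → EM for the MVN
(μ, Σ) → conditional-normal draws for the original missing cells), one
chain runs per completed panel with its own sub-seed, and the
multiple-imputation posterior is the pooled set of retained draws across
the m chains — the standard mixture-over-imputations representation of the
MI posterior. Per-panel summaries are retained alongside the pooled one.
Pooling draws matters: a single 2000-iteration independence chain in 16
dimensions accepts only a few per mille of its proposals (the posterior
occupies a tiny fraction of the 16-dimensional prior volume), so one
chain's empirical 95% interval is spanned by a handful of accepted points
and systematically under-covers; five chains with fresh starts and
between-imputation spread restore near-nominal coverage, which is what the
recovery study measures.

**Kalman oracle.** Conditional on x₁ the model is linear-Gaussian, so the
exact likelihood is a Gauss-Legendre mixture over x₁ ∈ (−3, 3) (128 nodes;
the integrand is a Gaussian in x₁, so the quadrature is exact for practical
purposes): one scalar Kalman recursion per node, sequential scalar updates
for the (diagonal-noise) indicators, missing rows skipped. Verified against
brute-force 3-dimensional grid integration on a T = 3 instance to 1e−6.
The oracle exists only for validation; the estimation path never uses it.

## Preprocessing

* **Mann-Kendall** trend test with tie-corrected variance and continuity
  correction, two-sided; missing entries are dropped (pairs over observed
  values only).
* **Sieve-bootstrap t-test** for a linear trend: OLS slope t-statistic,
  AR(p) sieve on the detrended residuals, bootstrap series rebuilt under
  the zero-slope null from resampled innovations (20-step spin-up so the
  series start from the AR stationary law). The sieve order is selected by
  BIC on a common conditioning sample with the cap p ≤ n/4, and the
  innovations are inflated for the degrees of freedom absorbed by the trend
  and AR fits. BIC rather than AIC: comparing AIC across unequal effective
  samples over-selects spurious lags on short independent series and makes
  the test anti-conservative (measured size 0.086 at nominal 0.05); the
  common-sample BIC version measures ~0.047 and the bootstrap p-value is
  invariant to affine rescaling of the input.
* **ADF** with constant + trend regression and AIC lag selection
  (statsmodels' MacKinnon p-values); `integration_order` differences up to
  twice and returns max_d + 1 when even the last difference fails to
  reject. Note the test has essentially no power at T ≈ 28; order
  determination is validated at longer series lengths.
* **Imputation**: linear interpolation (endpoints extended by the nearest
  observed value — interior interpolation is the defined behaviour, the
  ends need a convention) for trend checking; mean imputation for the
  supply covariates, refused at ≥ 40% missingness; EMB as above. EM
  convergence is ‖Δμ‖∞ + ‖ΔΣ‖∞ < 1e−6 with ridge regularization of a
  near-singular Σ; degenerate bootstrap resamples (a column with < 2
  observed cells) are redrawn.
* **Standardization** to observed-cell mean 0 / sd 1, with the transform
  stored for inversion; imputation happens on natural scales first.

## Factor analysis

Maximum-likelihood extraction on the correlation matrix of the d-times
differenced panel via the classical profiled likelihood: the discrepancy is
minimized over uniquenesses (L-BFGS-B, multi-start, uniqueness floor 0.005)
with the loadings concentrated out through the eigendecomposition.
Quartimin (oblique) rotation via statsmodels' gradient-projection routine;
the inter-factor correlation is reported. Sign convention: each factor is
oriented so its largest-magnitude loading is positive. With five series and
two factors the model has a single residual degree of freedom, so boundary
(Heywood) solutions are common (~40% of seeds in simulation); they are
flagged with a warning and do not harm loading or score recovery at the
communalities the generator produces. Bartlett scores are computed with the
differenced-fit loadings and uniquenesses applied to the undifferenced
standardized panel, so the score series retains all T time points; which of
the two factor scores feeds the state equation is configurable
(`factor_index`, default 1) since the construct-to-factor assignment is a
modelling choice, not an estimate.

By default d = 2 differences are applied to all five series, matching the
reference procedure, even though two of the series are integrated of order
one; per-series differencing is available.

## Synthetic data

The generators emulate the study conditions: T = 28 annual points
(1990-2017); five risk-factor series that are the d-fold cumulative sums
(d from {2,1,2,1,2} for obesity, tobacco, blood glucose, raised blood
pressure, cholesterol) of a stationary two-factor-plus-noise process plus
linear trends, with factor correlation 0.35; smooth trending covariates
(disability weights kept in (0,1) via a logistic map); and indicators
generated exactly from the state-space equations. Missingness is MCAR,
confined to the two utilization indicators (default 15%, always below the
40% threshold) and optionally to contiguous blocks of the two supply
covariates — the variables that were incomplete in the study. MCAR is the
weakest mechanism both imputation paths tolerate; the mechanism is not
otherwise constrained.

The idiosyncratic noise of the risk-factor series defaults to sd 0.3,
putting standardized communalities near 0.9 — the regime of smooth,
strongly collinear national prevalence series. This is also the regime in
which Bartlett scores are informative: at communalities much below ~0.8 the
score-truth correlation is bounded below 0.93 in population for a
5-series/2-factor design, so no estimator could track the factors closely.

Reference true parameters for recovery studies (`DEFAULT_TRUE_PARAMS`) were
fixed once inside the prior supports, with both utilization loadings
negative and all coefficient magnitudes ≥ 0.3 so sign-recovery checks are
meaningful. What the generator does **not** emulate: count-valued
indicators, the exact marginal distributions of the real national series,
measurement-system breaks, and MAR/MNAR missingness — so passing tests
demonstrate correctness of the estimators under the model's own
assumptions, not robustness to their violation.

## Diagnostics

Autocorrelation (ML normalization), effective sample size
n / (1 + 2 Σ ρ(k)) with the sum truncated at the first non-positive lag and
capped at n, and the Geweke early/late mean comparison (first 10% vs last
50%). Segment-mean variances use batch means with 20 batches; because each
variance estimate then carries ~19 degrees of freedom, the p-value uses a
Student-t reference with Welch-Satterthwaite degrees of freedom rather than
a normal — the normal reference is measurably anti-conservative at this
batch count. The RMSD-by-particle-count table predicts the indicators
noise-free from one filter pass and averages the root-mean-square
discrepancy over observed time points (t ≥ 2) and replicates.

## Reference problem sizes

The validation studies run at: 50 seeded filter runs at N = 1000 (T = 10)
for the likelihood-unbiasedness check; 4000-iteration chains and a 64×64
quadrature grid for the pseudo-marginal cross-check; 20 replicates ×
(EMB m = 5 → five 2000-iteration, N = 500 chains, 500 burn-in) at T = 28
for parameter recovery; n = 200 panels for factor and imputation recovery;
and 800-1500 simulations per test for the type-I-error calibrations. The
full-scale configuration (6250 iterations, N = 1000, m = 5) is the package
default for real analyses.

## Known limitations

* The prior-proposal independence sampler mixes poorly whenever the data
  are informative; with a single chain, credible intervals need far more
  than a few thousand iterations. The multiple-imputation pooling used here
  mitigates but does not remove this; a future random-walk or adaptive
  proposal would (deliberately out of scope, as the reference procedure is
  the independence sampler).
* ADF-based order determination is unreliable at T ≈ 28 (a property of the
  test, not of the implementation).
* The Kalman oracle covers only the linear-Gaussian model; any non-Gaussian
  extension would need a different validation route.
* Parameters are assumed static over the sample in PIMH; the online filter
  can in principle track drift, but the synthetic studies do not exercise
  time-varying truth.
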