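# burdenssm

State-space estimation of a latent chronic-disease burden index from annual
macro-level health series.

## The problem

Population burden from a non-communicable disease group (cardiovascular
disease, neoplasms, diabetes/kidney disease, chronic respiratory disease) is
not directly observable. It leaves traces in what causes it — risk-factor
prevalence, disease prevalence, disability weights — and in what it causes —
years of life lost (YLL) and health-service utilization. `burdenssm` treats
the burden as a scalar latent state `x_t` of a linear-Gaussian state-space
model over annual time points and estimates its trajectory and coefficients
jointly with two sequential Monte Carlo methods.

The model, on standardized series, is

```
x_t  = α₁ x_{t-1} + α₂ u1_t + α₃ u2_t + α₄ u3_t + α₅ u4_t + ε_t     ε_t  ~ N(0, σ²_s)
y1_t = θ₁ x_t                           + η1_t                      η1_t ~ N(0, σ²_m1)   (YLL)
y2_t = θ₂ x_t + θ₃ z2_t + θ₄ z3_t       + η2_t                      η2_t ~ N(0, σ²_m2)   (outpatients)
y3_t = θ₅ x_t + θ₆ z1_t + θ₇ z3_t       + η3_t                      η3_t ~ N(0, σ²_m3)   (hospital days)
```

with u1 a risk-factor factor score, u2 disease prevalence, u3/u4
mild-moderate/severe disability-weight averages, z1 beds, z2 specialists and
z3 GDP per capita. Inference is Bayesian under independent uniform priors
(positive coefficients on (0,1); θ₂, θ₅ on (−1,1); variances on (0.1,1.5);
x₁ on (−3,3)):

* **Online particle filter** — joint state + parameter filtering, with
  every static parameter given artificial random-walk dynamics
  (N(0, 0.01) jitter) so one 1000-particle sweep tracks all 16 parameters.
* **PIMH** (Particle Independent Metropolis-Hastings) — an independence
  sampler over the static parameters whose intractable likelihood is
  replaced by the particle filter's unbiased estimate (pseudo-marginal
  MCMC), run once per multiply-imputed panel and pooled.

An indicator that is missing at time t contributes a likelihood factor of
one, so the filter runs through gaps without imputation; supply covariates
are mean-imputed in the filter path and the PIMH path completes the panel
with EM-with-bootstrapping (EMB) multiple imputation. Upstream, the five
collinear risk-factor prevalences are trend-tested (Mann-Kendall,
sieve-bootstrap t), differenced to stationarity (ADF-guided), collapsed by
maximum-likelihood factor analysis with quartimin rotation, and converted to
Bartlett factor scores `η̂_t = (β'ω⁻¹β)⁻¹ β'ω⁻¹ y_t` that feed u1.

Everything is exercised on seeded synthetic data with known ground truth; an
exact Kalman filter (the model is linear-Gaussian) serves as the correctness
oracle for both Monte Carlo methods.

## Worked example

```python
import burdenssm as b

cfg = b.SyntheticConfig(T=28, seed=1)                 # 28 annual points
dataset, latent, panel = b.simulate_study(cfg, missing_indicators=True)

# exact likelihood vs the particle-filter estimate at the true parameters
kal = b.kalman_exact(dataset, cfg.true_params)
ll, xhat = b.pf_likelihood(dataset, cfg.true_params, N=1000, seed=3)
print(f"kalman {kal.log_likelihood:.2f}  pf {ll:.2f}")
# -> kalman -58.81  pf -58.88

import numpy as np
print(f"filtered-mean RMSE vs Kalman: "
      f"{np.sqrt(np.mean((xhat - kal.filtered_mean)**2)):.3f}")
# -> filtered-mean RMSE vs Kalman: 0.016

# online joint state+parameter estimation
fit = b.pf_online(dataset, N=1000, seed=5)
print({k: round(v, 2) for k, v in list(fit.final_parameters.to_dict().items())[:3]})
# -> {'alpha1': 0.44, 'alpha2': 0.52, 'alpha3': 0.6}
```

The two log-likelihoods agree to within Monte-Carlo error (the particle
estimate is unbiased for the exact one), the filtered trajectory matches the
exact filter to ~0.02 on the standardized burden scale, and the online
filter's final parameter estimates recover the signs and rough magnitudes of
the generator's coefficients.

The same flow is available from the shell:

```bash
burdenssm simulate --out run/ --seed 1
burdenssm tsfa --in run/riskfactors.csv --k 2 --d 2 --out run/scores.csv
burdenssm fit-pf --in run/dataset.csv --particles 1000 --seed 1 --out run/fit.json
burdenssm run-all --mode pimh --seed 1 --out run-pimh/
```

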