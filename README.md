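# recurcure

Joint frailty **mixture cure** models for **recurrent gap-time data** with
dependent censoring, estimated by Monte Carlo EM.

## The problem

In hospital-readmission and tumour-recurrence studies, patients experience
an event repeatedly; after each episode a fraction is effectively cured and
will never relapse. Cured patients look exactly like censored ones, and
because the chance of being cured and the pace of recurrence share
unobserved patient-level causes, censoring is informative. `recurcure`
models both mechanisms jointly for gap times (durations between successive
episodes):

* an **incidence** submodel for the probability of remaining susceptible
  after each recurrence, π_ij = g(V′γ + ω₂ᵢ), with a complementary
  log–log link g(η) = exp(−e^η) or a logistic link;
* a **latency** proportional-hazards submodel for susceptible gap times,
  λ(t) = λ₀(t)·exp(Z′β + ω₁ᵢ), with a nonparametric (Breslow-type)
  baseline;
* two **correlated, non-identical frailties** (ω₁ᵢ, ω₂ᵢ) per subject. In
  the clog–log variant, u₁ = x·y and u₂ = y/2 with x ~ Beta(α, α),
  y ~ Gamma(2α, α), giving mean-one gamma marginals and
  Corr(ω₁, ω₂) = √(ψ′(2α)/ψ′(α)); the logistic variant fixes the
  correlation at 1/√2. A shared-frailty ("identical") comparator is
  included.

A single heterogeneity parameter α drives the frailty variances. Estimation
is Monte Carlo EM: per-subject posterior frailty draws
(Metropolis-within-Gibbs), Newton updates for γ and β, a posterior-weighted
Breslow baseline, bounded scalar search for α, Louis-method standard
errors, and a Monte Carlo observed-data log-likelihood for AIC. The package
ships the matching data generator and a replicated-study harness
(mean/MSE/SE recovery tables, Harrell's C with a 70:30 split, AIC ranking).
See `docs/methods.md` for the full model and the numerical choices.

## Worked example

```python
import numpy as np
from recurcure import (SimulationConfig, simulate_dataset,
                       MCEMConfig, fit_cloglog, train_test_cindex)

cfg = SimulationConfig(n_subjects=500, gamma0=1.0, gamma=-5.0, beta=-4.0,
                       alpha=0.5, weibull_scale=3.0, weibull_shape=10.0)
ds = simulate_dataset(cfg, seed=7)

fit = fit_cloglog(ds.data, config=MCEMConfig(
    mcss=200, max_iter=80, seed=1,
    incidence_mode="binomial", latency_mode="extended"))

print("gamma :", np.round(fit.params.gamma, 3), "+/-", np.round(fit.se_gamma, 3))
print("beta  :", np.round(fit.params.beta, 3), "+/-", np.round(fit.se_beta, 3))
print("alpha :", round(fit.params.alpha, 3), "+/-", round(fit.se_alpha, 3))
print("AIC   :", round(fit.aic, 1))
print("C     :", tuple(round(c, 3) for c in
                       train_test_cindex(ds.data, fit.params.beta, seed=0)))
```

prints

```
gamma : [ 0.975 -5.324] +/- [0.153 0.514]
beta  : [-4.075] +/- [0.126]
alpha : 0.536 +/- 0.042
AIC   : 5898.8
C     : (0.65, 0.668)
```

The incidence intercept and slope sit near the generating values (1, −5):
the V = 1 group is almost surely susceptible while the V = 0 group is
cured about three-quarters of the time. The latency coefficient −4.08
(truth −4) says susceptible carriers of Z recur at e⁻⁴ times the baseline
hazard, and α̂ ≈ 0.54 indicates strong unobserved heterogeneity
(frailty variance ≈ 1/α̂ ≈ 1.9). Train and test concordance agree, so the
one-coefficient latency predictor is not overfitting.

The same models are available from the shell:

```bash
recurcure simulate --n 500 --gamma0 1 --gamma -5 --beta -4 --alpha 0.5 \
                   --scale 3 --shape 10 --seed 7 --out sim/
recurcure fit --data sim/records.csv --link cloglog --mcss 200 --seed 1 --out fit/
recurcure evaluate --data sim/records.csv --result fit/result.json --out eval/
```

Long-format CSV tables (one row per gap) are the data interface; an
adapter for the colorectal readmission layout (`id`, `t.start`, `t.stop`,
`event`, `chemo`, `sex`, `dukes`, `charlson`) is provided in
`recurcure.io.adapt_readmission_layout`.

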