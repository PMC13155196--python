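# Methods

`recurcure` implements joint frailty mixture cure models for recurrent
gap-time data with dependent censoring, their Monte Carlo EM estimators,
the matching data generator, and a replicated-study harness. This note
records the model, the estimation choices, the numerical conventions, and
what the synthetic studies do and do not demonstrate.

## Model

For subject i = 1..N and recurrence j = 1..n_i, the gap time t_ij (time
since the previous recurrence) carries an event indicator δ_ij (1 =
recurrence observed, 0 = censored). After each recurrence a latent cure
status U_ij ∈ {0, 1} is resolved: with probability

    π_ij = P(U_ij = 1 | ω_2i) = g(V_ij'γ + ω_2i)

the subject remains susceptible, where g is the complementary log–log link
g(η) = exp(−e^η) or the logistic link g(η) = e^η/(1+e^η). Susceptible
gaps follow a proportional-hazards latency model

    λ(t | U = 1, ω_1i) = λ0(t) exp(Z_ij'β + ω_1i),

with nonparametric cumulative baseline Λ0. Marginally on U, a gap survives
as S(t) = 1 − π + π·exp(−Λ0(t) e^{Z'β + ω_1}) — a mixture with a plateau
at the cure fraction 1 − π, which induces dependent censoring: subjects
likely to be cured are also likely to be censored.

The two frailties are correlated but not identical:

* **clog–log model.** x ~ Beta(α, α), y ~ Gamma(2α, rate α) independent;
  u1 = x·y (latency multiplier, Gamma(α, α) marginal), u2 = y/2
  (incidence multiplier, Gamma(2α, 2α) marginal); ω_k = log u_k. Both
  multipliers have mean 1 (identifiability with the baseline), variances
  1/α and 1/(2α), and Corr(ω1, ω2) = √(ψ′(2α)/ψ′(α)) > 0. Joint density
  (change of variables from the construction):
  f(u1, u2) = 2 α^{2α} u1^{α−1} (2u2 − u1)^{α−1} e^{−2α u2} / Γ(α)² on
  0 < u1 < 2u2.
* **logistic model.** With a = 1/α: u1 ~ Gamma(2a, rate a),
  u2 ~ Beta(a, a) independent; ω1 = log(u1·u2), ω2 = logit(u2). Then
  E[e^{ω1}] = 1, E[ω2] = 0 and Corr(ω1, ω2) = 1/√2 ≈ 0.707 for every α.
  By beta–gamma algebra u1·u2 ~ Gamma(a, rate a), so the marginal of ω1
  is log-gamma in closed form and −ω2 | ω1 is exactly
  log Gamma(a, rate a·e^{ω1}) — no numerical marginalisation is needed.
* **identical model (comparator).** A single shared u ~ Gamma(α, α) is
  both multipliers.

A single α governs all heterogeneity; α → ∞ is the homogeneous limit.

## Estimation

All three fits share one MCEM driver (`recurcure.mcem`).

**E-step.** Per subject, K draws from the posterior of the frailty pair
given that subject's records, by Metropolis-within-Gibbs with independence
proposals from the prior conditionals (exact in the no-data limit; cheap
because the per-subject likelihood reduces to a handful of sufficient
statistics). Chains are warm-started across EM iterations (burn-in 200 on
the first iteration, 30 afterwards); one state is retained after every
coordinate update. The latent cure statuses are Rao–Blackwellised: per
draw, a censored record's posterior non-cure is
Ū = πS1 / (1 − π(1 − S1)), and the M-steps consume E[U], E[U·m] and the
frailty sufficient statistics (m = e^{ω1} is the latency multiplier).

**M-steps** (block coordinate ascent on the expected complete-data
log-likelihood):

* γ by Newton–Raphson with analytic gradient/Hessian and step-halving;
* (β, Λ0) by alternating a posterior-weighted Breslow baseline update
  (risk sets on the gap-time scale, gaps exchangeable given the frailty;
  censored records weighted by E[U·m]; Breslow tie convention) with
  Newton steps on the expected latency objective;
* α by bounded scalar maximisation of the expected log frailty density on
  log α ∈ [log 10⁻³, log 10³].

Two variant forms of the incidence and latency objectives are kept as
config switches. `incidence_mode="double_weighted"` double-weights
uncensored records and adds a first-order censored survival term;
`latency_mode="events_only"` drops the censored cumulative-hazard terms.
The `"binomial"` / `"extended"` modes are the exact complete-data
expectations; they are what the study harness runs, because only they make
the truth a fixed point of the EM map (the variant forms bias γ and β,
which the harness records).

**Logistic two-stage estimator.** Stage 1 updates (β, Λ0) and α from the
event terms plus the frailty prior; stage 2 updates γ at frozen (β, α)
from the incidence terms. Two choices depart from the corresponding
first-order scheme and are deliberate:

* the censored contribution uses the exact log(1 − π(1 − S1)) rather than
  its first-order approximation −π(1 − S1). The approximation is bounded
  below by −1 per record while the exact term diverges for a clearly
  cured subject; under moderate cure rates the bounded penalty lets γ and
  the (unbounded below) frailty ω2 run away jointly. The approximation
  and its error bound |log(1−x)+x| ≤ x²/(2(1−x)) remain available as a
  diagnostic (`logistic_censored_approx_loglik`).
* stage 2 retains the event terms Σδ E[log π] (the event factor of the
  mixture density); without them the stage-2 objective is monotone in π
  and has no interior maximiser in γ.
* α maximises the expected **joint** frailty log-density (the conditional
  f(ω2|ω1) and marginal f(ω1) terms of the two stages combined). The
  conditional piece alone is not an EM ascent and drifts toward
  homogeneity.

**Zero-tail constraint.** Censored gaps beyond the last observed event
time take S1 = 0 in the posterior, the cure weights, and the observed
likelihood — the standard semiparametric mixture cure convention. Without
it the plateaued step baseline grossly overstates tail survival, treats
clearly cured subjects as at-risk, and biases γ0 and α.

**Standard errors** per block from the Louis identity
I = E[−B_c] − E[S_c S_c'] + S_m S_m' over the retained draws, with a
Bernoulli variance correction for the latent cure statuses; with one
degenerate draw and no censoring this collapses to the complete-data
observed information (finite-difference-checked in the tests). The
baseline is profiled out, so the SEs are mildly optimistic — the study
harness reports them next to across-replication SDs. Non-positive-definite
information falls back to a flagged pseudo-inverse.

**Observed-data log-likelihood and AIC.** Monte Carlo importance sampling
from the frailty prior (default 500 fresh draws per subject, log-sum-exp
combined); AIC = −2ℓ + 2(p + q + 1), baseline increments excluded by the
semiparametric convention. These AICs are comparable between the model
variants here but not with fully parametric AICs, and they carry both MC
noise and the usual downward Jensen bias of importance sampling (larger
for the two-dimensional frailty integral); model-comparison runs use more
draws to suppress it.

**Initialisation and convergence.** β starts at a no-frailty PH fit, γ at
a no-frailty GLM with δ as response proxy, α at 1. Convergence is declared
when the maximum absolute change of (β, γ, log α) stays below tol = 0.001
on two successive iterations. At Monte Carlo sample sizes of 100–1000 the
per-iteration MC jitter usually exceeds that tolerance, so fits run a
fixed outer-iteration budget and report the average of the last
`tail_avg = 10` iterates (Polyak-style); the strict flag is still
reported, and the harness drops only non-finite fits from its means.

## Data generator

`simulate_dataset` draws, per subject: a loss-to-follow-up time
C ~ Uniform(0, 5) (one abstract time unit; the censoring bound and the
Weibull baseline Λ0(t) = scale·t^shape live on the same scale), one
frailty pair, and subject-constant Bernoulli(1/2) covariates Z, V. Gaps
are generated by inverting the conditional survival; generation stops when
the cumulative time crosses C (censored, truncated) or a cure U = 0 is
drawn (one final censored record with the remaining time). Latent truths
are retained. The operational cure rate is the fraction of subjects whose
generation ended by U = 0; the record-level censoring fraction is reported
separately.

The generator reproduces exactly the mechanism the estimators assume:
per-subject frailty pairs, gap-time exchangeability, independent uniform
follow-up. It does not emulate calendar-time dynamics, covariates that
change between recurrences, terminal events competing with recurrence, or
measurement error in gap times — so passing recovery studies demonstrate
internal consistency of the estimators under the model, not robustness to
those real-data features.

## Study conditions and what the studies show

The harness replicates three reference conditions at N = 1000 with 20
replications (desk scale; 250 replications are a config change):

1. clog–log, truth (γ0, γ, β, α) = (1, 2.5, −1, 1.5), Weibull(1, 1.5),
   MCSS = 100.
2. clog–log, truth (1, −5, −4, 0.5), Weibull(3, 10), MCSS = 1000.
3. logistic, truth (1, 1, −0.01, 0.91), Weibull(2, 15), MCSS = 100.

Outer-iteration budgets (150 / 85 / 120) are sized so the EM trajectories
reach their plateaus at these sample sizes on a single CPU.

Condition 1 deserves a caveat: under these parameter values roughly 96% of
subjects are cured and a replication carries only ~40–50 events, and
susceptible draws among V = 1 subjects are so rare (probability ≈ 6·10⁻⁴)
that the incidence coefficient γ is quasi-separated — its maximum
likelihood estimate diverges and the EM drifts upward without bound, while
α and γ0 are weakly identified. The harness reports what the estimator
actually does under this condition. Condition 2 and 3 recoveries are
genuine: β is recovered essentially unbiasedly everywhere, and α within
finite-sample bias that vanishes by N = 4000 (checked during development
at four-fold sample size).

Evaluation metrics: Harrell's concordance index of the latency linear
predictor Z'β̂ (frailty excluded — population-level discrimination) on a
subject-level 70:30 split, and AIC ranking across model variants.

## Numerical conventions

* Gamma distributions are shape–rate throughout (Gamma(α, α) has mean 1).
* Links evaluated in log space (no NaN for |η| ≤ 700); censored mixture
  terms via log1p with the product π(1−S1) capped at 1 − 10⁻¹⁶.
* Beta draws clipped to the open unit interval (10⁻¹⁶ margins);
  log(2u2 − u1) computed as log y + log1p(−x) from the construction
  coordinates.
* Breslow ties: shared risk set, event count in the numerator.
* All randomness flows from a single integer seed through
  `numpy.random.default_rng`; identical (data, config, seed) give
  byte-identical fits.

## Known limitations

* Louis SEs ignore baseline-estimation uncertainty (profile convention).
* The observed-data likelihood is a Monte Carlo estimate; AIC differences
  within a few points are below its resolution at the default draw count.
* Fixed 1/√2 frailty correlation in the logistic model (by construction);
  the clog–log correlation is a function of α alone.
* Per-record fixed covariates only; no left truncation or interval
  censoring; no terminal-event submodel (death acts only through C and
  the cure mechanism).
* At small event counts or extreme cure fractions (condition 1 above) the
  incidence block can be separated; the fit then reports the drifting
  trajectory honestly rather than guarding it.
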