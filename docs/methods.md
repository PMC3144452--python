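# Methods

This note documents the statistical model behind `stratcox`, the defaults it
ships with and why, the numerical choices inside the solver, and what the
simulation design can and cannot tell you about real cohort data.

## Data-generating process

The synthetic target population is a working cohort followed for myocardial
infarction. Each individual belongs to one of three occupational strata —
professionals, technicians, administrative staff — and is a smoker or not.
Event times follow a Weibull proportional-hazards model: with shape k and
scale σ the baseline cumulative hazard is H₀(t) = (t/σ)ᵏ, an individual with
linear predictor η has survival S(t) = exp(−H₀(t)·e^η), and times are drawn
by the inverse transform

    T = σ · (−ln U / e^η)^(1/k),   U ~ Uniform(0,1).

The linear predictor is η = stratum main effect + smoker × stratum-specific
smoking effect; there is no common smoking main effect, so smoking acts
entirely through its interaction with stratum. Everyone enters at time zero
and survivors are administratively censored at the 40-year horizon.

### Default parameters

| parameter | default | units | rationale |
|---|---|---|---|
| population size | 52,750 | people | size of the emulated occupational cohort |
| strata proportions | 0.505 / 0.28 / 0.215 | — | professionals / technicians / administrative |
| smoking prevalence | 0.159 / 0.209 / 0.253 | — | rises with decreasing occupational category |
| stratum HR vs professionals | 1 / 1.5 / 3 | hazard ratio | socioeconomic gradient in MI hazard |
| smoking HR within stratum | 1.5 / 2.0 / 3.0 | hazard ratio | effect heterogeneity across strata |
| Weibull shape k | 2 | — | increasing hazard with age, plausible for MI |
| Weibull scale σ | 40/√(−ln 0.85) ≈ 99.22 | years | calibrated so a professional non-smoker has a 15% event probability by 40 years |
| censoring horizon | 40 | years | administrative end of follow-up |

The cohort structure (strata, prevalences, hazard ratios, horizon) pins down
everything except the Weibull pair (k, σ); those two are genuinely free and
are therefore explicit, mandatory fields of `PopulationSpec`, so any other
calibration can be swapped in. With these defaults roughly 13,500 of the
52,750 individuals (~26%) experience the event inside the horizon.

Integer stratum sizes come from largest-remainder apportionment of the
proportions (exact total, deterministic; 52,750 → 26,639 / 14,770 / 11,341).
Smoking is an independent Bernoulli draw within stratum — only marginal
prevalences are specified, so independence is the natural completion. Times
are kept continuous (no rounding to whole years): ties then occur with
probability zero and the Breslow tie convention is innocuous.

## Sampling designs and weights

Two designs are implemented, both without replacement:

* **simple random**: n from N, weight N/n for everyone;
* **stratified, non-proportional**: n_h from N_h within each stratum, weight
  N_h/n_h. The default allocation (3,000 / 4,500 / 7,500 out of a 15,000
  sample) heavily oversamples the administrative stratum, giving weights
  26,639/3,000 ≈ 8.880, 14,770/4,500 ≈ 3.282 and 11,341/7,500 ≈ 1.512.

Weights are always computed from the realized integer stratum counts, never
hard-coded, so the Horvitz–Thompson identity Σwᵢ = N holds to floating
precision on every draw. No finite-population correction is applied in
variance estimation; with sampling fractions up to 2/3 in the oversampled
stratum the sandwich variances are therefore conservative for the
fixed-population target.

## Loss to follow-up

Loss is modelled as event suppression: among records with an observed event,
each is independently selected with the applicable rate and converted to a
censored record *at the same observed time*. Two scenarios are bundled:
15% random loss (non-informative: the thinning is independent of covariates,
so weighted estimates stay consistent and only precision degrades) and
stratum-differential loss of 8% / 12% / 20% (informative: the highest-hazard
stratum loses most events, dragging its estimated hazard down in every model
specification). Rates are interpreted as fractions of *event* individuals —
that is the reading under which the two scenarios produce exactly the random
versus informative censoring behaviours the design intends. An alternative
mechanism that redraws the dropout time uniformly before the event is
available behind `LossSpec(mechanism="uniform_dropout")` for sensitivity
analysis; it is never the default.

## Weighted Cox estimation

The estimating function is the design-weighted partial-likelihood score
(Binder-style): U(β) = Σᵢ wᵢδᵢ[xᵢ − S⁽¹⁾(tᵢ;β)/S⁽⁰⁾(tᵢ;β)] with weighted
risk-set sums S⁽ʳ⁾. Properties maintained by construction and verified by
tests: constant weights reproduce the classical unweighted estimate;
rescaling all weights by a positive constant changes neither β̂ nor the
sandwich covariance; a weight of 2 is equivalent to duplicating the record
(point estimates).

Numerical choices:

* **Newton–Raphson with step-halving** (up to 30 halvings per step); a step
  is accepted only if it does not decrease the log partial likelihood.
* **Convergence**: relative change in log partial likelihood < 1e-9, at most
  50 iterations. Oracle-equivalence tests tighten this to ~1e-14, where the
  solver matches an independent implementation to ~1e-11.
* **Ties**: Breslow. Simulated times are continuous so ties are
  measure-zero; Breslow keeps the weighted score in closed form.
* **Degenerate fits**: zero events, non-positive weights and non-finite
  inputs are rejected up front; a singular information matrix raises an
  error naming the offending columns; a fit whose largest |log-HR| exceeds
  15 at convergence is declared a monotone-likelihood (perfect separation)
  failure and raises with the full iteration trace.
* **Variance**: both the model-based inverse information and the
  design-based sandwich I⁻¹MI⁻¹ are always computed, with M the
  outer-product sum of weighted score residuals
  rᵢ = δᵢ(xᵢ−x̄(tᵢ)) − e^{ηᵢ} Σ_{events k: tₖ≤tᵢ} (wₖ/S⁽⁰⁾(tₖ))(xᵢ−x̄(tₖ)).
  With unit weights the sandwich coincides with the Lin–Wei robust variance
  (cross-checked against lifelines to ~1e-13 and against a delete-one
  jackknife within a factor 1.5 at n = 30).

Hazard ratios are non-collapsible: dropping a prognostic covariate from a
Cox model attenuates the remaining coefficients toward the null even when
the dropped covariate is independent of them. At this population's event
fractions the attenuation is small (~0.6% on the crude smoking HR in the
no-confounding configuration), but it is why "marginal" and "crude" hazard
ratios are defined as what the census fit of the corresponding specification
estimates, not as algebraic averages of the generating values.

## Monte-Carlo design and its interpretation

All replicates of all scenarios sample from **one** fixed generated
population. Bias is therefore measured against that population's census fit
of the same model specification (the "population parameter" for that
specification) — for misspecified models the generating parameters are not
even the right target. Replicate means converge to census values, which
themselves sit within census-fit sampling error of the generating values;
parameter-recovery checks against generating values accordingly use the
combined error √(census SE² + replication SE²).

Seeding: one root seed per scenario; replicate r derives its sampling stream
from `SeedSequence(root, spawn_key=(r, 0))` and its loss stream from
`(r, 1)`, so each replicate is reproducible in isolation and results do not
depend on execution order. Scenarios sharing a root seed and design reuse
identical samples, making comparisons across models, weightings and loss
scenarios paired — deliberately, as it sharpens contrasts such as the strict
variance inflation under random loss.

Summaries per coefficient: mean log-HR and mean HR over replicates, bias on
the log-HR scale, empirical variance (R−1 divisor), the average of the
per-replicate *estimated* variances (sandwich for weighted fits, model-based
for unit-weight fits — the two natural choices for each), and
MSE = empirical variance + bias², which holds as an exact identity in the
output. A scenario is flagged when the census value falls outside the
central 95% (2.5th–97.5th percentile) of its replicate estimates.
Non-converged replicates are excluded and counted; more than 5% aborts the
scenario. Sampling distributions are displayed with a Gaussian kernel
density using the classic Silverman bandwidth 0.9·min(sd, IQR/1.34)·n^(−1/5)
unless overridden.

Scales: the bundled full-scale configuration (`configs/paper_default.yaml`)
runs the complete 2 designs × 3 models × 2 weightings × 3 loss grid at 2,000
replicates of 15,000. The test suite and worked examples run the same
pipeline at 200 replicates — the package's desk-scale default, which leaves
Monte-Carlo standard errors small enough for the 3-SE checks the tests make.

## What the generator does and does not emulate

The generator reproduces the features that drive design effects: strong
non-proportional allocation, covariate-by-stratum effect heterogeneity, a
socioeconomic hazard gradient aligned with exposure prevalence, and
informative versus non-informative attrition. It does **not** emulate age at
entry (everyone starts at time zero), competing risks, time-varying
covariates or hazards that violate proportionality, measurement error,
clustered sampling, or covariate-dependent dropout *within* stratum. Passing
tests therefore demonstrate correctness of the estimators and the direction
and rough magnitude of design-induced biases under proportional hazards —
not that any particular real cohort's bias will match these magnitudes.

## Known limitations

* The three model specifications are fixed codings of this cohort's two
  covariates; the fitter itself is general, but the spec-builder is not a
  formula interface.
* No time-varying weight recalculation at dropout and no sub-distribution
  (competing-risk) hazards; informative censoring is only *diagnosed* here,
  not corrected.
* The sandwich variance targets the superpopulation; no finite-population
  correction is offered.
* Efron tie handling is not implemented (continuous times make it moot for
  the bundled studies).
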