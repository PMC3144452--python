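# stratcox

Design-weighted Cox regression under non-proportional stratified sampling
and loss to follow-up: a Monte-Carlo simulation toolkit for biostatistics
and epidemiology.

Large cohort studies often select participants by stratified sampling with
*non-proportional* allocation — oversampling small but scientifically
important subgroups — and then lose participants over decades of follow-up.
Both features can bias hazard-ratio estimates from a Cox proportional-hazards
model if they are ignored. `stratcox` lets you quantify that bias: it
generates a synthetic occupational cohort with known hazard structure, draws
samples under simple-random or stratified designs, imposes random or
stratum-differential loss to follow-up, fits weighted and unweighted Cox
models of three nested specifications, and summarizes bias, variance and
mean squared error of the hazard-ratio estimates over replications.

## The model

Event times follow a Weibull proportional-hazards model. With baseline
cumulative hazard H₀(t) = (t/σ)ᵏ and linear predictor

η = β₁·tech + β₂·admin + γ₁·(prof × smoking) + γ₂·(tech × smoking) + γ₃·(admin × smoking),

times are drawn by inverse transform, T = σ·(−ln U / e^η)^{1/k}, and
administratively censored at 40 years. The default population has 52,750
individuals in three occupational strata — professionals (50.5%),
technicians (28%), administrative staff (21.5%) — smoking prevalence
15.9% / 20.9% / 25.3% by stratum, stratum hazard ratios 1 / 1.5 / 3 and
within-stratum smoking hazard ratios 1.5 / 2.0 / 3.0.

Estimation uses the design-weighted partial-likelihood score

U(β) = Σᵢ wᵢ δᵢ [xᵢ − S⁽¹⁾(tᵢ;β)/S⁽⁰⁾(tᵢ;β)],  S⁽ʳ⁾(t;β) = Σ_{j:tⱼ≥t} wⱼ e^{xⱼᵀβ} xⱼ^{⊗r},

with wᵢ the inverse selection probability (N_h/n_h within stratum h), solved
by Newton–Raphson with Breslow tie handling, and the design-based sandwich
covariance I⁻¹MI⁻¹ built from weighted score residuals. Three model
specifications are available: **full** (stratum effects + stratum-specific
smoking effects, the generating structure), **marginal** (stratum effects +
one common smoking effect) and **smoke-only** (the crude smoking effect).

## Worked example

```python
import numpy as np
from stratcox import (PopulationSpec, DesignSpec, LossSpec, ModelSpec,
                      ScenarioSpec, generate_population,
                      population_reference_fit, run_replications, summarize)

pop = generate_population(PopulationSpec(), seed=12345)
census = population_reference_fit(pop, ModelSpec("marginal"))
print(dict(zip(census.names, np.round(census.hr, 3))))
# {'technicians': 1.607, 'administrative': 3.668, 'smoking': 2.15}

design = DesignSpec("stratified", allocation={
    "professionals": 3000, "technicians": 4500, "administrative": 7500})
for weighting in ("weighted", "unweighted"):
    sc = ScenarioSpec(weighting, design, LossSpec("none"), ModelSpec("marginal"),
                      weighting, replicates=200, seed=777)
    summ = summarize(run_replications(pop, sc), census)
    row = summ.set_index("coefficient").loc["smoking"]
    print(f"{weighting:10s} mean smoking HR {row.mean_hr:.3f}  "
          f"MSE {row.mse:.5f}  excludes census value: {row.excludes_reference}")
# weighted   mean smoking HR 2.157  MSE 0.00110  excludes census value: False
# unweighted mean smoking HR 2.592  MSE 0.03529  excludes census value: True
```

The census (whole-population) marginal fit puts the pooled smoking hazard
ratio at 2.15. Sampling 15,000 people with the administrative stratum
heavily oversampled and fitting *without* the design weights pushes the mean
estimate to 2.59 — the replicate distribution no longer even covers the true
value — while the weighted fit stays centred at the cost of some variance.
That is the core phenomenon this package measures.

A full study (population → census fits → scenario grid → summaries,
comparison report and figures) runs from a YAML config:

```bash
stratcox run-study --config configs/tiny.yaml           # minute-scale smoke run
stratcox run-study --config configs/paper_default.yaml  # full 36-scenario grid, R=2000
```

Individual pipeline stages are exposed as `stratcox generate-population`,
`draw-sample`, `apply-loss`, `fit`, `replicate`, `summarize` and
`make-fixtures`; all take explicit `--seed` values and are bit-reproducible.

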