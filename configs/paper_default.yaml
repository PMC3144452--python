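# Full-scale study: 52,750-person population, 2 designs x 3 models x
# 2 weightings x 3 loss scenarios, 2,000 replicates of n = 15,000 each.
# Expect multi-hour runtime on one CPU; see configs/tiny.yaml for a
# minute-scale smoke version.
seed: 20110626
output_dir: study_output
verbosity: info
plots: true
population:
  population_size: 52750
  strata_labels:
  - professionals
  - technicians
  - administrative
  strata_proportions:
  - 0.505
  - 0.28
  - 0.215
  smoking_prevalence:
  - 0.159
  - 0.209
  - 0.253
  stratum_log_hr:
  - 0.0
  - 0.4054651081081644
  - 1.0986122886681098
  smoking_log_hr_by_stratum:
  - 0.4054651081081644
  - 0.6931471805599453
  - 1.0986122886681098
  weibull_shape: 2.0
  weibull_scale: 99.22200869260435
  censor_horizon: 40.0
scenarios:
- name: srs_full_weighted_noloss
  design: &id001
    kind: simple_random
    sample_size: 15000
  loss: &id002
    mode: none
  model: full
  weighting: weighted
  replicates: 2000
- name: srs_full_weighted_randloss
  design: *id001
  loss: &id003
    mode: random
    rate: 0.15
  model: full
  weighting: weighted
  replicates: 2000
- name: srs_full_weighted_diffloss
  design: *id001
  loss: &id004
    mode: differential
    rates_by_stratum:
      professionals: 0.08
      technicians: 0.12
      administrative: 0.2
  model: full
  weighting: weighted
  replicates: 2000
- name: srs_full_unweighted_noloss
  design: *id001
  loss: *id002
  model: full
  weighting: unweighted
  replicates: 2000
- name: srs_full_unweighted_randloss
  design: *id001
  loss: *id003
  model: full
  weighting: unweighted
  replicates: 2000
- name: srs_full_unweighted_diffloss
  design: *id001
  loss: *id004
  model: full
  weighting: unweighted
  replicates: 2000
- name: srs_marginal_weighted_noloss
  design: *id001
  loss: *id002
  model: marginal
  weighting: weighted
  replicates: 2000
- name: srs_marginal_weighted_randloss
  design: *id001
  loss: *id003
  model: marginal
  weighting: weighted
  replicates: 2000
- name: srs_marginal_weighted_diffloss
  design: *id001
  loss: *id004
  model: marginal
  weighting: weighted
  replicates: 2000
- name: srs_marginal_unweighted_noloss
  design: *id001
  loss: *id002
  model: marginal
  weighting: unweighted
  replicates: 2000
- name: srs_marginal_unweighted_randloss
  design: *id001
  loss: *id003
  model: marginal
  weighting: unweighted
  replicates: 2000
- name: srs_marginal_unweighted_diffloss
  design: *id001
  loss: *id004
  model: marginal
  weighting: unweighted
  replicates: 2000
- name: srs_smoke_only_weighted_noloss
  design: *id001
  loss: *id002
  model: smoke_only
  weighting: weighted
  replicates: 2000
- name: srs_smoke_only_weighted_randloss
  design: *id001
  loss: *id003
  model: smoke_only
  weighting: weighted
  replicates: 2000
- name: srs_smoke_only_weighted_diffloss
  design: *id001
  loss: *id004
  model: smoke_only
  weighting: weighted
  replicates: 2000
- name: srs_smoke_only_unweighted_noloss
  design: *id001
  loss: *id002
  model: smoke_only
  weighting: unweighted
  replicates: 2000
- name: srs_smoke_only_unweighted_randloss
  design: *id001
  loss: *id003
  model: smoke_only
  weighting: unweighted
  replicates: 2000
- name: srs_smoke_only_unweighted_diffloss
  design: *id001
  loss: *id004
  model: smoke_only
  weighting: unweighted
  replicates: 2000
- name: strat_full_weighted_noloss
  design: &id005
    kind: stratified
    allocation:
      professionals: 3000
      technicians: 4500
      administrative: 7500
  loss: *id002
  model: full
  weighting: weighted
  replicates: 2000
- name: strat_full_weighted_randloss
  design: *id005
  loss: *id003
  model: full
  weighting: weighted
  replicates: 2000
- name: strat_full_weighted_diffloss
  design: *id005
  loss: *id004
  model: full
  weighting: weighted
  replicates: 2000
- name: strat_full_unweighted_noloss
  design: *id005
  loss: *id002
  model: full
  weighting: unweighted
  replicates: 2000
- name: strat_full_unweighted_randloss
  design: *id005
  loss: *id003
  model: full
  weighting: unweighted
  replicates: 2000
- name: strat_full_unweighted_diffloss
  design: *id005
  loss: *id004
  model: full
  weighting: unweighted
  replicates: 2000
- name: strat_marginal_weighted_noloss
  design: *id005
  loss: *id002
  model: marginal
  weighting: weighted
  replicates: 2000
- name: strat_marginal_weighted_randloss
  design: *id005
  loss: *id003
  model: marginal
  weighting: weighted
  replicates: 2000
- name: strat_marginal_weighted_diffloss
  design: *id005
  loss: *id004
  model: marginal
  weighting: weighted
  replicates: 2000
- name: strat_marginal_unweighted_noloss
  design: *id005
  loss: *id002
  model: marginal
  weighting: unweighted
  replicates: 2000
- name: strat_marginal_unweighted_randloss
  design: *id005
  loss: *id003
  model: marginal
  weighting: unweighted
  replicates: 2000
- name: strat_marginal_unweighted_diffloss
  design: *id005
  loss: *id004
  model: marginal
  weighting: unweighted
  replicates: 2000
- name: strat_smoke_only_weighted_noloss
  design: *id005
  loss: *id002
  model: smoke_only
  weighting: weighted
  replicates: 2000
- name: strat_smoke_only_weighted_randloss
  design: *id005
  loss: *id003
  model: smoke_only
  weighting: weighted
  replicates: 2000
- name: strat_smoke_only_weighted_diffloss
  design: *id005
  loss: *id004
  model: smoke_only
  weighting: weighted
  replicates: 2000
- name: strat_smoke_only_unweighted_noloss
  design: *id005
  loss: *id002
  model: smoke_only
  weighting: unweighted
  replicates: 2000
- name: strat_smoke_only_unweighted_randloss
  design: *id005
  loss: *id003
  model: smoke_only
  weighting: unweighted
  replicates: 2000
- name: strat_smoke_only_unweighted_diffloss
  design: *id005
  loss: *id004
  model: smoke_only
  weighting: unweighted
  replicates: 2000
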