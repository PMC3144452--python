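# Minute-scale smoke study: 2,000-person population, 20 replicates.
seed: 99
output_dir: tiny_output
verbosity: warning
plots: false
population:
  population_size: 2000
scenarios:
- name: strat_full_weighted
  design:
    kind: stratified
    allocation:
      professionals: 150
      technicians: 200
      administrative: 250
  loss:
    mode: none
  model: full
  weighting: weighted
  replicates: 20
- name: strat_marginal_unweighted
  design:
    kind: stratified
    allocation:
      professionals: 150
      technicians: 200
      administrative: 250
  loss:
    mode: differential
    rates_by_stratum:
      professionals: 0.08
      technicians: 0.12
      administrative: 0.2
  model: marginal
  weighting: unweighted
  replicates: 20
- name: srs_smoke_only_weighted
  design:
    kind: simple_random
    sample_size: 600
  loss:
    mode: random
    rate: 0.15
  model: smoke_only
  weighting: weighted
  replicates: 20
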