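# Full-pipeline configuration (all blocks optional; defaults shown in
# qintreg.pipeline.DEFAULT_CONFIG).
data:
  graph: namibia13          # fixture name or path to a tab-separated edge list
  simulate:                 # or:  path: my_survey.csv
    n_per_year: 800
model:
  fixed_covariates: [urban, improved_water, improved_toilet, television,
                     male_head, male_child, wealth, education]
  smooth_terms:
    child_age_months: RW2
    preceding_birth_interval_months: RW1
  spatial: PCAR             # ICAR | PCAR | IID | none
  temporal: RW1
mcmc:
  iterations: 6000
  burn_in: 1000
grid:
  tau_star: 0.92
  delta: 0.07
  step: 0.01
  weights: uniform          # or: triangular
selection:
  enabled: false
output: {}
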