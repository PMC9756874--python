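# Example roe-deer demographic configuration for `rewild pva`.
#
# SYNTHETIC / non-authoritative: literature-plausible rates for a mid-size
# temperate cervid, assembled for demonstration.  The demographic parameter
# set behind any particular published projection was not deposited; replace
# these values with your own before drawing conclusions.
initial_individuals:
  - {sex: F, age: 2, n: 19}
  - {sex: M, age: 2, n: 18}
age_classes:
  - {min_age: 0, max_age: 0, survival_female: 0.65, survival_male: 0.65}
  - {min_age: 1, max_age: 1, survival_female: 0.80, survival_male: 0.75}
  - {min_age: 2, max_age: 12, survival_female: 0.88, survival_male: 0.82}
breeding_proportion: 0.80
litter_distribution: {1: 0.35, 2: 0.55, 3: 0.10}
sex_ratio_at_birth: 0.5
first_breeding_age: 2
carrying_capacity: 400
years: 19
iterations: 100
seed: 7
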