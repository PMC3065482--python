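attribute_subsets:
- - group
  - disease
- - group
  - treatment
- - disease
  - treatment
- - group
  - disease
  - treatment
bootstrap_replicates: 1000
cohort:
  attribute_frequencies:
    disease:
      CNS: 0.07
      GI: 0.15
      GYN: 0.12
      H&N: 0.09
      breast: 0.16
      leukemia: 0.11
      lung: 0.14
      melanoma: 0.07
      prostate: 0.09
    group:
      CALGB: 0.12
      CHOG: 0.07
      ECOG: 0.3
      GOG: 0.11
      NCCTG: 0.09
      RTOG: 0.13
      SWOG: 0.18
    treatment:
      adjuvant: 0.24
      definitive: 0.28
      induction: 0.16
      maintenance: 0.12
      other: 0.09
      supportive: 0.11
  hr_model:
    body_location: 0.05
    body_scale: 0.25
    tail_exponent: 2.8
    tail_mass: 0.05
    tail_xmin: 1.5
  n_trials: 280
  seed: 0
  significance_model:
    events_max: 800
    events_min: 50
    jitter_sd: 0.3
    p_floor: 1.0e-12
  year_range:
  - 1955
  - 2006
er_replicates: 5
master_seed: 0
n_bins: 20
n_permutations: 10000
output_dir: study_output
pa:
  degree_weighted: false
  m: 18
  m0: 19
  score_rule: hr_times_one_minus_p
  seed: 0
tail_min: 10
top_k: 10
trials_csv: null
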