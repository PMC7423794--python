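# A small, fast demonstration run (a few thousand model evaluations,
# well under a minute end to end). For analysis-scale runs raise the
# cohort sizes and PSA draw count.
seed: 7
cohort:
  n_t1dm: 300
  n_t2dm: 600
  followup_years: 10.0
survival:
  candidates: [hba1c, duration, sbp, tchol]
  alpha: 0.05
  use_longitudinal: true
  longitudinal_max_subjects: 400
analysis:
  discount_rate: 0.035
  discount_rate_sensitivity: 0.015
  threshold: 20000.0
  horizon_age: 100.0
scenarios:
  hba1c_percent: [6.5, 8.0, 9.5]
  t1dm_duration_years: [3.0, 9.0, 15.0]
  t2dm_duration_years: [1.5, 4.5, 8.0]
psa:
  n_draws: 100
paths:
  output_dir: out
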