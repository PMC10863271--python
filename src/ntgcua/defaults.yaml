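# Base-case parameter set: 10-year Markov cost-utility model of treating
# mild normal-tension glaucoma in China.  Costs in 2023 USD.
transitions:
  p_mild_to_moderate_positive: 0.044
  p_moderate_to_severe_positive: 0.018
  p_mild_to_moderate_traditional: 0.149
  p_moderate_to_severe_traditional: 0.056
utilities:
  u_mild: 0.80
  u_moderate: 0.75
  u_severe: 0.71
  u_dead: 0.0
mortality:
  bands:
    - [65, 69, 0.00364]
    - [70, 74, 0.00518]
  glaucoma_odds_ratio: 1.8
  # Published base case: entry-band rate held over the horizon, odds ratio
  # available but not folded into the base-case transition matrix.
  apply_odds_ratio: false
  band_mode: entry
costs:
  annual_dual_therapy: 307.24
  annual_triple_therapy: 470.45
  trabeculectomy: 530.97
  followup_no_progression: 79.55
  followup_progression: 119.32
  first_year_moderate_B: 381.84
  first_year_severe_B: 381.84
  consecutive_year_moderate_B: 254.56
  consecutive_year_severe_B: 254.56
  dual_to_triple_ratio: 3.0
  dose_multiplier_after_progression: 1.5
  surgical_failure_rate: 0.20
econ:
  discount_rate: 0.035
  horizon: 10
  start_age: 64.0
  cohort_size: 100000
  gdp_per_capita: 12692.90
  half_cycle_correction: true
  half_cycle_method: trapezoid
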