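name: feedback-strong
description: >
  Strong treatment-confounder feedback: selection into treatment on uric
  acid is twice as strong as in recovery-A, the treatment lowers uric acid
  by a steady-state -2 mg/dL, and uric acid drives death more strongly.
  The naive unweighted estimate is badly biased relative to the
  counterfactual oracle (true marginal HR near 0.5); inverse-probability
  weighting removes the bias.
dgp:
  n_patients: 2000
  T: 36
  seed: 0
  baseline_treat_coefs: {intercept: -1.43, ua: -1.2, alb: -0.6}
  treat_coefs: {intercept: -4.6, prev_treatment: 7.5, ua: -1.2, alb: -0.6}
  ua_treatment_effect: -0.4
  outcome_coefs: {intercept: -5.15, treatment: -1.39, ua: -0.5, alb: -0.5}
  cvd_coefs: {intercept: -4.4, treatment: -0.08, ua: -0.10, alb: -0.20}
  dropout_hazard: 0.0029
  missing_rate: 0.0
propensity:
  time_dependent: [ua, alb]
  baseline: [age, sex_male, bmi, diabetes]
outcome:
  outcome: death
  time_terms: linear
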