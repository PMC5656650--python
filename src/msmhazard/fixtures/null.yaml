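name: "null"
description: >
  Confounded treatment assignment (low uric acid and low albumin both raise
  the probability of treatment) but a treatment with no effect on labs or
  hazards: the true marginal hazard ratio is exactly 1.  Sized for repeated
  replication (1000 patients, 12 monthly visits).
dgp:
  n_patients: 1000
  T: 12
  seed: 0
  treat_coefs: {intercept: -4.6, prev_treatment: 7.5, ua: -0.45, alb: -0.25}
  ua_treatment_effect: 0.0
  outcome_coefs: {intercept: -5.15, treatment: 0.0, ua: -0.25, alb: -0.35}
  cvd_coefs: {intercept: -4.4, treatment: 0.0, ua: -0.10, alb: -0.20}
  dropout_hazard: 0.0029
  missing_rate: 0.0
propensity:
  time_dependent: [ua, alb]
  baseline: [age, sex_male, bmi, diabetes]
outcome:
  outcome: death
  time_terms: linear
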