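name: recovery-A
description: >
  Moderate treatment-confounder feedback: treatment lowers uric acid
  (steady-state shift -1.5 mg/dL), low uric acid and low albumin predict
  both future treatment and death, and the direct treatment effect is set so
  that the counterfactual marginal hazard ratio is close to 0.5.  The naive
  unweighted estimate is biased toward the null; the IPTW-weighted estimate
  recovers the oracle.
dgp:
  n_patients: 2000
  T: 36
  seed: 0
  baseline_treat_coefs: {intercept: -1.43, ua: -0.8, alb: -0.4}
  treat_coefs: {intercept: -4.6, prev_treatment: 7.5, ua: -0.8, alb: -0.4}
  ua_treatment_effect: -0.3
  outcome_coefs: {intercept: -5.15, treatment: -1.045, ua: -0.35, alb: -0.45}
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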