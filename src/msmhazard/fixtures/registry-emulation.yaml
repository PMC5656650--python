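name: registry-emulation
description: >
  Full-size study conditions: 2429 patients over 36 monthly visits, ~19%
  treated at baseline with the rate decreasing across uric-acid quintiles,
  roughly 19% three-year mortality and 10% dropout, and 8% per-visit lab
  missingness handled by last-observation-carried-forward.  Used by the CLI
  as the default simulation target.
dgp:
  n_patients: 2429
  T: 36
  seed: 0
  treat_coefs: {intercept: -4.6, prev_treatment: 7.5, ua: -0.45, alb: -0.25}
  ua_treatment_effect: -0.3
  outcome_coefs: {intercept: -5.15, treatment: -0.97, ua: -0.25, alb: -0.35}
  cvd_coefs: {intercept: -4.4, treatment: -0.08, ua: -0.10, alb: -0.20}
  dropout_hazard: 0.0029
  missing_rate: 0.08
propensity:
  time_dependent: [ua, alb, npcr, cgr, ferritin, na, ktv]
  baseline: [age, sex_male, bmi, diabetes, hd_vintage]
outcome:
  outcome: death
  time_terms: linear
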