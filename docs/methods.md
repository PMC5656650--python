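# Methods

## The problem

In maintenance haemodialysis cohorts, uric-acid-lowering treatment (xanthine
oxidoreductase inhibitors) is prescribed in response to serum uric acid (UA),
which the treatment itself lowers, and which — together with albumin — also
predicts mortality.  This is *treatment–confounder feedback*: a time-varying
covariate lies on the causal path from past treatment to future treatment and
outcome.  Conditioning on such a covariate in an ordinary regression blocks
part of the treatment effect and opens collider paths, so neither adjusting
nor not adjusting gives the causal answer.  Marginal structural models (MSMs)
estimated by inverse probability of treatment weighting (IPTW) handle exactly
this situation: each person-visit is reweighted so that, in the pseudo-
population, treatment at every visit is independent of the measured
time-varying confounders, after which a simple marginal model of outcome on
treatment has a causal interpretation.

## Estimation procedure

1. **Treatment (denominator) model.**  A pooled logistic regression over all
   person-visit rows of current treatment A_t on previous treatment A_{t−1},
   baseline covariates, and previous-visit labs (UA, albumin by default).
   At visit 1 the baseline treatment indicator and baseline lab values stand
   in for the unavailable lag.  One pooled fit is used rather than 36
   per-visit fits: the visit enters through the lagged covariates, and
   pooling is far more stable at moderate cohort sizes.
2. **Numerator model.**  The same regression without the time-dependent labs
   (previous treatment and baseline covariates only).
3. **Stabilized weights.**  Per visit, each model's fitted probability is
   converted to the probability of the treatment actually received (p if
   treated, 1−p if not).  Cumulative products over visits 1..t give the
   numerator and the inverse denominator; their product is the stabilized
   weight SW_t.  E[SW_t] = 1 when the denominator model is correct, so the
   pooled mean near 1 is a standing diagnostic.
4. **Truncation (sensitivity).**  Weights outside the mirrored (100−p)th /
   p-th percentile bounds of the pooled person-visit weights (p = 95 or 99)
   are reset to the bounds.  Percentiles are order statistics (numpy
   `method="lower"`/`"higher"`), which makes truncation exactly idempotent.
5. **Outcome model.**  A weighted pooled logistic regression of the monthly
   event indicator on an intercept, month terms and *current* treatment,
   with the stabilized (or truncated) weight as the observation weight.  The
   exponentiated treatment coefficient is the hazard ratio: with monthly
   event probabilities of order 10⁻², the discrete-time pooled logistic
   model is the standard approximation to a marginal structural Cox model.
   Month enters scaled as month/T, linearly by default; subgroup (quintile)
   analyses use the cubic polynomial (m, m², m³) specification, which is the
   appropriate reduced model when events are sparse.
6. **Inference.**  Cluster-robust (sandwich) covariance with patients as
   clusters throughout the pooled fits — a patient contributes up to T
   correlated rows.  Wald 95% CIs on the log-HR scale.

The unweighted fit of the same outcome model is always reported alongside as
the naive comparator.

No inverse-probability-of-censoring weights are applied: dropout is simulated
(and modelled) as independent of the evolving state, and patients are simply
dropped at censoring.  The report flags this.  Subgroup (quintile) analyses
reuse the all-cohort weights; refitting weights within quintile is possible
by restricting the panel first.

## Statistical primitives

The four estimation primitives are implemented directly rather than wrapped:

* **Weighted logistic regression** by Fisher scoring / IRLS; convergence when
  the largest absolute coefficient update is below 1e−8 (at most 100
  iterations); separation flagged when any |coefficient| exceeds 50; rank
  deficiency detected by QR before iteration and reported with the offending
  column names.  Model covariance is the inverse weighted information;
  robust covariance is the cluster sandwich (score sums per cluster).
* **Cox proportional hazards** by Newton–Raphson on the Breslow-ties partial
  likelihood, with the Lin–Wei robust covariance built from score residuals
  summed within cluster.  Breslow is used because it is the default of the
  major commercial survival procedure and the tie structure here (monthly
  grids) is modest.
* **Kaplan–Meier** product-limit curve; censored subjects at t remain in the
  risk set for events at t.
* **k-group log-rank test** from hypergeometric moments at each distinct
  event time, chi-square on k−1 df (generalised inverse for the covariance
  of the first k−1 groups, so empty groups cannot break it).

statsmodels and lifelines appear only in the test suite, as independent
cross-checks of these implementations (tie-free data for the Cox check,
where Breslow and Efron coincide).

## The synthetic cohort generator

Because no registry data ship with the package, cohorts are simulated with
the causal structure above.  Per patient and month, on a fixed 1..T monthly
grid (T = 36 by default):

* **Baselines** echo a Japanese maintenance-haemodialysis population: age
  67.3 ± 12.4 y, 66.4% male, BMI 21.8 ± 3.8, 40.7% diabetic, dialysis
  vintage lognormal with mean 74.6 months, UA 7.3 ± 1.3 mg/dL, albumin
  3.6 ± 0.4 g/dL, plus nPCR, CGR, ferritin, sodium and KT/V as realistic
  noise labs and a small roster of comorbidity flags.
* **Treatment**: Bernoulli with logit θ₀ + θ₁A_{t−1} + θ₂z(UA_{t−1}) +
  θ₃z(Alb_{t−1}).  θ₁ = 7.5 encodes strong prescription persistence
  (continuation ≈ 0.95, initiation ≈ 0.01 monthly), matching how standing
  prescriptions behave; the baseline treatment rate is ≈ 19% and decreases
  across UA quintiles (≈ 30% in the lowest to ≈ 10% in the highest under
  the registry-emulation settings).
* **Labs**: stationary AR(1) around the population mean with autocorrelation
  0.8; innovation SDs chosen to reproduce the marginal SDs.  Treatment
  shifts UA additively each treated month (sustained shift =
  effect/(1−ρ), e.g. −1.5 mg/dL under continuous treatment in recovery-A).
* **Death and first CVD event**: monthly Bernoulli hazards with logit
  β₀ + γA_t + β_UA z(UA_t) + β_Alb z(Alb_t); β₀ = −5.15 gives ≈ 19%
  three-year mortality.  The CVD channel reuses the death machinery with a
  higher base rate; only the first event is recorded and patients remain at
  risk of death afterwards.
* **Dropout**: independent monthly Bernoulli (0.0029 ≈ 10% over 3 years).
* **Missingness**: applied last, per lab per visit, to the recorded values
  only (dynamics use the true values); LOCF restores completeness.

All randomness is pre-drawn from one seed, so equal config + seed gives a
bit-identical panel.

**Ground truth** comes from counterfactual simulation: the same baseline and
innovation draws are replayed with treatment forced always-on and always-off
(common random numbers, no dropout), and the marginal hazard ratio is read
from an unweighted pooled logistic fit to the stacked arms.  This oracle is
what the observational MSM estimate is judged against.

### Named fixtures

* `null` — confounded assignment, zero treatment effect (true HR exactly 1);
  1000 patients × 12 visits, sized for replication studies.
* `recovery-A` — moderate feedback; direct effect calibrated once by
  counterfactual simulation so the oracle HR ≈ 0.5 (0.507 at n = 150 000).
  Naive deviation from the oracle ≈ +0.10 on the log scale.
* `feedback-strong` — selection on UA and the UA pathway strengthened so the
  naive estimator's deviation exceeds 0.15 on the log scale (+0.18 measured
  over 100 seeds) while the weighted estimator stays within ±0.10 (−0.01
  measured).  This pair of facts is the package's core validation.
* `registry-emulation` — full-size conditions (2429 × 36) with 8%
  missingness and the full lab roster; the CLI's default simulation target.

The calibration of these effect sizes was performed once, by simulation, and
frozen into the YAML files; they are study conditions, not tuning knobs.

### What the generator does not emulate

Real registries have informative censoring, measurement error, drug dosage
and switching, recurrent CVD events, and confounders outside the recorded
labs.  Passing the benchmark therefore shows the estimator chain is correct
under its own assumptions (sequential exchangeability given the modelled
history, correct model forms), not that those assumptions hold in any real
cohort.

## Numerical choices

* Month terms scaled by 1/T before entering designs (conditioning).
* Constant design columns in degenerate settings (e.g. a single-visit panel
  makes the month column constant) are dropped from the outcome model rather
  than allowed to trigger rank errors; the treatment column is never
  dropped.
* Propensity predictions are clamped into [1e−10, 1−1e−10] before inversion
  (with a logged count); an exact 0 or 1 prediction is an error.
* Quintile ties: patients sharing a boundary UA value all take the lower
  quintile, making the assignment a deterministic function of the UA value
  and invariant to strictly monotone transforms.
* LOCF back-fills leading missingness from the first observed value so that
  retained rows are complete; patients with a never-observed lab are dropped
  and logged.

## Problem sizes used in validation

Component checks run on closed-form worked examples.  The simulation checks
use: 200 replications of `null` (1000 × 12) for CI coverage; 100 seeds of
2000 × 36 per confounded fixture against an oracle computed at n = 150 000;
weight diagnostics at 2000 × 36; reference-library agreement on 50 random
small datasets.  `scripts/acceptance.py` re-runs the same analyses at
moderately reduced replication counts (25 replicate cohorts, oracle at
60 000, 100 null replications) so a full from-scratch reproduction stays
inside a coffee break on one CPU.

## Known limitations

* No inverse-probability-of-censoring weighting; fine under the simulated
  independent dropout, wrong if censoring is informative.
* Breslow ties only; Efron/exact methods are out of scope.
* The outcome model takes current-visit treatment as the exposure, not
  cumulative exposure; effects are assumed constant on the log-hazard scale.
* Stabilized-weight numerators include baseline covariates while the default
  outcome model adjusts only for treatment and time; with rare monthly
  events the resulting estimand is numerically indistinguishable from the
  marginal one (and exactly so when baseline covariates carry no outcome
  signal), but a `adjust_baseline` list on the outcome spec exposes the
  fully conditional variant.
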