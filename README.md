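# msmhazard

Marginal structural models (MSMs) for the causal effect of a **time-varying
binary treatment** on survival in longitudinal cohorts — built around the
motivating case of uric-acid-lowering therapy (xanthine oxidoreductase
inhibitors) in maintenance haemodialysis patients, where prescription
responds to serum uric acid, the drug lowers uric acid, and uric acid and
albumin predict both future prescribing and death.  Under this
*treatment–confounder feedback*, ordinary regression is biased no matter
what it adjusts for; inverse probability of treatment weighting (IPTW) is
the standard remedy.

The package is aimed at biostatisticians and epidemiologists who want a
tested, reproducible implementation of the full chain: panel handling and
LOCF imputation, descriptive survival analysis (Kaplan–Meier, log-rank,
baseline Cox with robust SEs), stabilized-weight construction with
truncation and diagnostics, the weighted discrete-time outcome model, and a
synthetic cohort generator with a counterfactual ground-truth oracle for
validating the whole pipeline.

## The model

For patient *i* at monthly visit *t* (t = 1..T), with treatment indicator
A_t, covariate history L̄_t and baseline covariates V, the stabilized weight
is

    SW_i(t) = Π_{k≤t}  P(A_k | A_{k−1}, V)  /  P(A_k | A_{k−1}, V, L_{k−1})

with both conditional probabilities fitted by pooled logistic regression
(the numerator omits the time-dependent labs).  The causal hazard ratio is
then the exponentiated treatment coefficient of the weighted pooled logistic
outcome model

    logit P(Y_t = 1 | A_t) = α₀ + f(t) + ψ·A_t ,   weight = SW(t),

the discrete-time approximation of a marginal structural Cox model; f(t) is
linear in month (or cubic for sparse subgroups) and inference uses a
patient-clustered sandwich covariance.  Mean SW ≈ 1 is the standing
diagnostic; weights can be truncated at mirrored 95th/99th-percentile
bounds as a sensitivity analysis.

## Worked example

```python
import msmhazard as mh

fix = mh.load_fixture("recovery-A")          # 2000 patients, 36 visits
panel = mh.generate_cohort(fix.dgp)          # confounded observational cohort
model = mh.MarginalStructuralModel(panel, propensity=fix.propensity,
                                   outcome=fix.outcome)
res = model.fit()
print(res.summary())
```

```
Marginal structural model (discrete-time pooled logistic)
============================================================
outcome: death   weights: stabilized   time terms: linear
person-visits: 61995   events: 379   patients: 2000
------------------------------------------------------------
IPTW-weighted HR: 0.57 (95% CI 0.41-0.8)
naive (unweighted) HR: 0.62 (95% CI 0.48-0.81)
------------------------------------------------------------
stabilized weights over 61995 person-visits: mean 1.01, SD 0.642 (min 0.0252, max 21.8), 95% point 1.57, 99% point 3.32
```

The fixture's true marginal hazard ratio — computable here because the
generator can replay the same randomness under always-treat vs never-treat —
is ≈ 0.5:

```python
mh.oracle_marginal_hr(fix.dgp, n_large=100_000)   # ≈ 0.50
```

Averaged over replicate cohorts the weighted estimate centres on the oracle
while the naive one is biased toward the null by ~10% (and by ~20% on the
`feedback-strong` fixture); single cohorts scatter around those centres, as
the confidence intervals above indicate.  `res.quintile_effects()` gives
per-uric-acid-quintile estimates and `res.truncation_sensitivity()` the
none/95/99 truncation table.

## Command line

```bash
msmhazard simulate --fixture registry-emulation --seed 1 --out panel.csv
msmhazard run --fixture recovery-A --seed 1 --out report/
msmhazard weights --input panel.csv --out weights.csv
msmhazard msm --input panel.csv --weights weights.csv --outcome death
```

`run` writes a deterministic bundle: per-quintile descriptives (ANOVA /
chi-square), Kaplan–Meier curve data and log-rank tests, a baseline Cox
table with robust SEs, stabilized-weight diagnostics, and the MSM effect
table with truncation sensitivity.

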