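"""Synthetic longitudinal dialysis cohorts with treatment-confounder feedback.

The generator emulates a 3-year (36 monthly visits) haemodialysis registry:
a binary uric-acid-lowering treatment whose prescription depends on the
previous month's treatment and labs, serum labs that evolve by first-order
autoregression with treatment lowering uric acid, and discrete-time Bernoulli
hazards for death, first cardiovascular (CVD) event and dropout.  This is the
classic g-methods setting: past treatment changes a lab (uric acid) that
drives both future treatment and death, so naive regression is biased and
inverse-probability weighting is required.

Ground truth is provided by counterfactual simulation: the same baseline and
innovation draws are replayed under treatment forced always-on and always-off
(:func:`generate_counterfactual_arms`), and :func:`oracle_marginal_hr` turns
the two arms into a marginal discrete-time hazard ratio by an unweighted
pooled logistic fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace, asdict

import numpy as np
import pandas as pd
from scipy.special import expit

from .errors import ConfigError, ZeroEventsError
from .panel import CohortPanel
from . import estimation

__all__ = [
    "DGPConfig",
    "CounterfactualArms",
    "generate_cohort",
    "generate_counterfactual_arms",
    "oracle_marginal_hr",
]

#: labs that enter the causal structure (everything else is realistic noise)
CAUSAL_LABS = ["ua", "alb"]
NOISE_LABS = ["npcr", "cgr", "ferritin", "na", "ktv"]


def _default_baseline_params():
    # marginal moments chosen to echo a Japanese maintenance-haemodialysis
    # registry: elderly, two-thirds male, ~40% diabetic, UA 7.3 +/- 1.3 mg/dL
    return {
        "age_mean": 67.3, "age_sd": 12.4,
        "male_p": 0.664,
        "bmi_mean": 21.8, "bmi_sd": 3.8,
        "diabetes_p": 0.407,
        "vintage_mean": 74.6, "vintage_sd": 84.2,  # months, lognormal
        "ua_mean": 7.3, "ua_sd": 1.3,
        "alb_mean": 3.6, "alb_sd": 0.4,
        "npcr_mean": 0.87, "npcr_sd": 0.17,
        "cgr_mean": 91.5, "cgr_sd": 26.8,
        "ferritin_mean": 96.9, "ferritin_sd": 113.5,  # lognormal
        "na_mean": 137.9, "na_sd": 2.1,
        "ktv_mean": 1.4, "ktv_sd": 0.3,
        "comorbidity_p": {
            "cm_hypertensive_disease": 0.755,
            "cm_ischaemic_heart_disease": 0.327,
            "cm_pckd": 0.130,
        },
    }


@dataclass
class DGPConfig:
    """Full parameterisation of the synthetic data-generating process.

    Lab coefficients in the treatment and outcome models are on the
    standardised (per-SD) scale of the previous/current lab value; the
    treatment effect on uric acid (``ua_treatment_effect``) is an additive
    mg/dL shift per treated month, so the sustained shift under continuous
    treatment is ``ua_treatment_effect / (1 - ar_rho)``.
    """

    n_patients: int = 2429
    T: int = 36
    seed: int = 0
    baseline_params: dict = field(default_factory=_default_baseline_params)
    # P(treated at baseline) on the logit scale, labs standardised
    baseline_treat_coefs: dict = field(default_factory=lambda: {
        "intercept": -1.43, "ua": -0.50, "alb": -0.20})
    # P(treated at visit t | history), labs from visit t-1
    treat_coefs: dict = field(default_factory=lambda: {
        "intercept": -4.6, "prev_treatment": 7.5, "ua": -0.45, "alb": -0.25})
    ar_rho: float = 0.8
    ua_treatment_effect: float = -0.3  # mg/dL per treated month
    # monthly death hazard on the logit scale, labs from visit t (standardised)
    outcome_coefs: dict = field(default_factory=lambda: {
        "intercept": -5.15, "treatment": -0.95, "ua": -0.25, "alb": -0.35})
    cvd_coefs: dict = field(default_factory=lambda: {
        "intercept": -4.4, "treatment": -0.08, "ua": -0.10, "alb": -0.20})
    dropout_hazard: float = 0.0029  # per month, ~10% over 36 months
    missing_rate: float = 0.0       # per lab per visit

    def __post_init__(self):
        if self.n_patients < 1 or self.T < 1:
            raise ConfigError("n_patients and T must be positive")
        for name, p in [("dropout_hazard", self.dropout_hazard),
                        ("missing_rate", self.missing_rate)]:
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"{name} must be a probability, got {p}")
        if not -1.0 < self.ar_rho < 1.0:
            raise ConfigError(f"ar_rho must be in (-1, 1), got {self.ar_rho}")

    def with_(self, **kwargs) -> "DGPConfig":
        return replace(self, **kwargs)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class CounterfactualArms:
    """The two counterfactual worlds defining the marginal estimand."""

    panel_always: CohortPanel
    panel_never: CohortPanel
    shared_draws: bool = True


def _innov_sd(marginal_sd: float, rho: float) -> float:
    """Innovation SD giving the requested stationary marginal SD."""
    return marginal_sd * np.sqrt(1.0 - rho ** 2)


def _draw(config: DGPConfig, rng: np.random.Generator, lean: bool,
          with_treatment_draws: bool = True) -> dict:
    """Pre-draw every random quantity so arms can share randomness."""
    n, T = config.n_patients, config.T
    bp = config.baseline_params
    labs = CAUSAL_LABS if lean else CAUSAL_LABS + NOISE_LABS
    d = {"labs": labs}
    d["age"] = rng.normal(bp["age_mean"], bp["age_sd"], n).clip(18, 100)
    d["sex_male"] = (rng.uniform(size=n) < bp["male_p"]).astype(int)
    d["bmi"] = rng.normal(bp["bmi_mean"], bp["bmi_sd"], n).clip(12, 45)
    d["diabetes"] = (rng.uniform(size=n) < bp["diabetes_p"]).astype(int)
    mu, sd = bp["vintage_mean"], bp["vintage_sd"]
    s2 = np.log1p((sd / mu) ** 2)
    d["hd_vintage"] = rng.lognormal(np.log(mu) - s2 / 2, np.sqrt(s2), n)
    if not lean:
        d["cm"] = {name: (rng.uniform(size=n) < p).astype(int)
                   for name, p in bp["comorbidity_p"].items()}
    else:
        d["cm"] = {}
    base = {}
    base["ua"] = rng.normal(bp["ua_mean"], bp["ua_sd"], n).clip(1.0, None)
    base["alb"] = rng.normal(bp["alb_mean"], bp["alb_sd"], n).clip(1.5, None)
    if not lean:
        base["npcr"] = rng.normal(bp["npcr_mean"], bp["npcr_sd"], n).clip(0.2, None)
        base["cgr"] = rng.normal(bp["cgr_mean"], bp["cgr_sd"], n).clip(10, None)
        fmu, fsd = bp["ferritin_mean"], bp["ferritin_sd"]
        fs2 = np.log1p((fsd / fmu) ** 2)
        base["ferritin"] = rng.lognormal(np.log(fmu) - fs2 / 2, np.sqrt(fs2), n)
        base["na"] = rng.normal(bp["na_mean"], bp["na_sd"], n)
        base["ktv"] = rng.normal(bp["ktv_mean"], bp["ktv_sd"], n).clip(0.3, None)
    d["base_labs"] = base
    d["u_base_treat"] = rng.uniform(size=n)
    d["innov"] = {lab: rng.standard_normal((n, T)) for lab in labs}
    if with_treatment_draws:
        d["u_treat"] = rng.uniform(size=(n, T))
    d["u_death"] = rng.uniform(size=(n, T))
    d["u_cvd"] = rng.uniform(size=(n, T))
    d["u_drop"] = rng.uniform(size=(n, T))
    if config.missing_rate > 0 and not lean:
        d["u_miss"] = {lab: rng.uniform(size=(n, T)) for lab in labs}
    return d


def _lab_mean_sd(config: DGPConfig, lab: str) -> tuple:
    bp = config.baseline_params
    return bp[f"{lab}_mean"], bp[f"{lab}_sd"]


def _check_finite(eta: np.ndarray, coefs: dict, what: str) -> None:
    if not np.all(np.isfinite(eta)):
        raise ConfigError(
            f"non-finite linear predictor in the {what} model; "
            f"check coefficients {coefs}"
        )


def _simulate(config: DGPConfig, draws: dict,
              forced_treatment: int | None = None,
              with_dropout: bool = True,
              with_missing: bool = True) -> CohortPanel:
    n, T = config.n_patients, config.T
    labs = draws["labs"]
    th = config.treat_coefs
    oc = config.outcome_coefs
    cv = config.cvd_coefs
    rho = config.ar_rho

    bt = config.baseline_treat_coefs
    ua_m, ua_s = _lab_mean_sd(config, "ua")
    alb_m, alb_s = _lab_mean_sd(config, "alb")
    base = draws["base_labs"]
    z_ua0 = (base["ua"] - ua_m) / ua_s
    z_alb0 = (base["alb"] - alb_m) / alb_s
    if forced_treatment is None:
        p0 = expit(bt["intercept"] + bt["ua"] * z_ua0 + bt["alb"] * z_alb0)
        A0 = (draws["u_base_treat"] < p0).astype(int)
    else:
        A0 = np.full(n, forced_treatment, dtype=int)

    cur = {lab: base[lab].copy() for lab in labs}
    A_prev = A0
    active = np.ones(n, dtype=bool)
    had_cvd = np.zeros(n, dtype=bool)

    rec_active = np.zeros((n, T), dtype=bool)
    rec_A = np.zeros((n, T), dtype=int)
    rec_death = np.zeros((n, T), dtype=int)
    rec_cvd = np.zeros((n, T), dtype=int)
    rec_cens = np.zeros((n, T), dtype=int)
    rec_labs = {lab: np.full((n, T), np.nan) for lab in labs}

    for t in range(T):
        if not active.any():
            break
        z_ua_prev = (cur["ua"] - ua_m) / ua_s
        z_alb_prev = (cur["alb"] - alb_m) / alb_s
        if forced_treatment is None:
            eta = (th["intercept"] + th["prev_treatment"] * A_prev
                   + th["ua"] * z_ua_prev + th["alb"] * z_alb_prev)
            _check_finite(eta, th, "treatment")
            A = (draws["u_treat"][:, t] < expit(eta)).astype(int)
        else:
            A = np.full(n, forced_treatment, dtype=int)
        for lab in labs:
            m, s = _lab_mean_sd(config, lab)
            innov = _innov_sd(s, rho) * draws["innov"][lab][:, t]
            cur[lab] = m + rho * (cur[lab] - m) + innov
            if lab == "ua":
                cur[lab] = cur[lab] + config.ua_treatment_effect * A
            if not np.all(np.isfinite(cur[lab])):
                raise ConfigError(f"non-finite values in lab {lab!r} dynamics")
        z_ua = (cur["ua"] - ua_m) / ua_s
        z_alb = (cur["alb"] - alb_m) / alb_s
        eta_d = (oc["intercept"] + oc["treatment"] * A
                 + oc["ua"] * z_ua + oc["alb"] * z_alb)
        _check_finite(eta_d, oc, "death")
        death = draws["u_death"][:, t] < expit(eta_d)
        eta_c = (cv["intercept"] + cv["treatment"] * A
                 + cv["ua"] * z_ua + cv["alb"] * z_alb)
        _check_finite(eta_c, cv, "cvd")
        cvd_new = (draws["u_cvd"][:, t] < expit(eta_c)) & ~had_cvd
        if with_dropout and config.dropout_hazard > 0:
            drop = (draws["u_drop"][:, t] < config.dropout_hazard) & ~death
        else:
            drop = np.zeros(n, dtype=bool)

        rec_active[:, t] = active
        rec_A[:, t] = A
        rec_death[:, t] = death & active
        rec_cvd[:, t] = cvd_new & active
        rec_cens[:, t] = drop & active
        for lab in labs:
            rec_labs[lab][:, t] = cur[lab]

        had_cvd |= cvd_new & active
        active = active & ~death & ~drop
        A_prev = A

    mask = rec_active
    pid_grid = np.repeat(np.arange(n)[:, None], T, axis=1)
    visit_grid = np.tile(np.arange(1, T + 1), (n, 1))
    rows = {
        "patient_id": pid_grid[mask],
        "visit": visit_grid[mask],
        "treatment": rec_A[mask],
        "event_death": rec_death[mask],
        "event_cvd": rec_cvd[mask],
        "censored": rec_cens[mask],
    }
    baseline_cols = {
        "age": draws["age"], "sex_male": draws["sex_male"],
        "bmi": draws["bmi"], "diabetes": draws["diabetes"],
        "hd_vintage": draws["hd_vintage"], "baseline_treatment": A0,
        "baseline_ua": base["ua"],
    }
    for lab in labs:
        baseline_cols[f"baseline_{lab}"] = base[lab]
    for name, vals in draws["cm"].items():
        baseline_cols[name] = vals
    for name, vals in baseline_cols.items():
        rows[name] = np.repeat(vals[:, None], T, axis=1)[mask]
    for lab in labs:
        vals = rec_labs[lab].copy()
        if (with_missing and config.missing_rate > 0
                and "u_miss" in draws):
            vals[draws["u_miss"][lab] < config.missing_rate] = np.nan
        rows[lab] = vals[mask]
    df = pd.DataFrame(rows)
    df["patient_id"] = df["patient_id"].astype(int)
    return CohortPanel(df, T=T, validate=False)


def generate_cohort(config: DGPConfig) -> CohortPanel:
    """Generate one observational cohort; bit-identical for equal config+seed."""
    rng = np.random.default_rng(config.seed)
    draws = _draw(config, rng, lean=False)
    return _simulate(config, draws)


def generate_counterfactual_arms(config: DGPConfig,
                                 lean: bool = False) -> CounterfactualArms:
    """Replay the same randomness under always-treat and never-treat.

    Both arms share baseline and innovation draws (common random numbers);
    only the treatment path differs.  Counterfactual arms have no dropout and
    no missingness, since the estimand is defined on complete follow-up.
    ``lean=True`` skips the non-causal noise labs (useful at oracle scale).
    """
    rng = np.random.default_rng(config.seed)
    draws = _draw(config, rng, lean=lean, with_treatment_draws=False)
    panel_always = _simulate(config, draws, forced_treatment=1,
                             with_dropout=False, with_missing=False)
    panel_never = _simulate(config, draws, forced_treatment=0,
                            with_dropout=False, with_missing=False)
    return CounterfactualArms(panel_always, panel_never, shared_draws=True)


def oracle_marginal_hr(config: DGPConfig, n_large: int | None = None,
                       time_terms: str = "linear") -> float:
    """Ground-truth marginal hazard ratio by counterfactual simulation.

    Generates both counterfactual arms (at ``n_large`` patients when given),
    stacks them, and fits an UNWEIGHTED pooled logistic model of the monthly
    death indicator on an arm indicator plus month terms.  The exponentiated
    arm coefficient is the marginal discrete-time hazard ratio that the MSM
    on observational data targets.
    """
    cfg = config if n_large is None else config.with_(n_patients=n_large)
    arms = generate_counterfactual_arms(cfg, lean=True)
    parts = []
    for arm_val, panel in ((1, arms.panel_always), (0, arms.panel_never)):
        d = panel.data
        n_ev = int(d["event_death"].sum())
        if n_ev == 0:
            raise ZeroEventsError(
                f"no deaths in the {'always' if arm_val else 'never'}-treated "
                "arm; increase n_large or the baseline hazard"
            )
        parts.append(pd.DataFrame({
            "y": d["event_death"].to_numpy(),
            "month": d["visit"].to_numpy(),
            "arm": arm_val,
        }))
    stacked = pd.concat(parts, ignore_index=True)
    m = stacked["month"].to_numpy() / cfg.T
    cols = [np.ones(len(stacked)), m]
    names = ["intercept", "month"]
    if time_terms == "cubic":
        cols += [m ** 2, m ** 3]
        names += ["month2", "month3"]
    cols.append(stacked["arm"].to_numpy(dtype=float))
    names.append("arm")
    X = np.column_stack(cols)
    fit = estimation.fit_logistic(stacked["y"].to_numpy(dtype=float), X,
                                  column_names=names)
    return float(np.exp(fit.coefficients[-1]))
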