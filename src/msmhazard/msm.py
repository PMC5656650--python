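"""Weighted discrete-time outcome models and the MarginalStructuralModel API.

The causal hazard ratio of a time-varying binary treatment is estimated by a
*weighted pooled logistic regression*: stack every person-visit row, regress
the event indicator on an intercept, month terms and the current treatment,
weight each row by its stabilized inverse-probability-of-treatment weight,
and read the exponentiated treatment coefficient as the hazard ratio (the
standard discrete-time approximation to a marginal structural Cox model when
monthly event probabilities are small).  Confidence intervals use the
cluster-robust sandwich with patients as clusters, since a patient
contributes up to T correlated rows.

Two entry points are provided:

* functional: :func:`fit_msm`, :func:`run_quintile_analysis`,
  :func:`sensitivity_truncation` operating on a panel plus a
  :class:`~msmhazard.iptw.WeightSet`;
* object-oriented: :class:`MarginalStructuralModel` built from a panel,
  whose :meth:`~MarginalStructuralModel.fit` returns an :class:`MSMResults`
  carrying estimates, weight diagnostics and a ``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import norm

from .errors import ConfigError, EstimationError, ZeroEventsError
from .estimation import LogisticFit, fit_logistic
from .iptw import (
    PropensitySpec,
    WeightSet,
    compute_stabilized_weights,
    fit_denominator_model,
    fit_numerator_model,
    truncate_weights,
    weight_diagnostics,
)
from .panel import CohortPanel, assign_ua_quintiles, locf_impute

__all__ = [
    "OutcomeModelSpec",
    "EffectEstimate",
    "fit_msm",
    "run_quintile_analysis",
    "sensitivity_truncation",
    "MarginalStructuralModel",
    "MSMResults",
]

_Z95 = 1.959963984540054  # standard normal 97.5% quantile


@dataclass
class OutcomeModelSpec:
    """What to fit: outcome, time terms, weights and subgroup.

    time_terms 'linear' enters month/T; 'cubic' enters month, month^2 and
    month^3 (on the month/T scale) — the reduced specification used for
    sparse-event subgroup analyses.  weight_source 'none' is the naive
    (unweighted) comparator.
    """

    outcome: str = "death"           # 'death' or 'cvd'
    time_terms: str = "linear"       # 'linear' or 'cubic'
    weight_source: str = "stabilized"  # stabilized | truncated-95 | truncated-99 | none
    subgroup: int | None = None      # UA quintile 1..5, or None for all
    adjust_baseline: list = field(default_factory=list)  # extra covariates

    def __post_init__(self):
        if self.outcome not in ("death", "cvd"):
            raise ConfigError(f"unknown outcome {self.outcome!r}")
        if self.time_terms not in ("linear", "cubic"):
            raise ConfigError(f"unknown time_terms {self.time_terms!r}")
        ok = ("stabilized", "truncated-95", "truncated-99", "none")
        if self.weight_source not in ok:
            raise ConfigError(f"weight_source must be one of {ok}")
        if self.subgroup is not None and self.subgroup not in range(1, 6):
            raise ConfigError("subgroup must be a quintile 1..5 or None")


@dataclass
class EffectEstimate:
    """A log-hazard-ratio with cluster-robust uncertainty."""

    log_hr: float
    robust_se: float
    n_events: int
    n_person_visits: int
    spec: OutcomeModelSpec
    model_fit: LogisticFit | None = None

    @property
    def hr(self) -> float:
        return float(np.exp(self.log_hr))

    @property
    def ci_lower(self) -> float:
        return float(np.exp(self.log_hr - _Z95 * self.robust_se))

    @property
    def ci_upper(self) -> float:
        return float(np.exp(self.log_hr + _Z95 * self.robust_se))

    @property
    def p_value(self) -> float:
        z = self.log_hr / self.robust_se
        return float(2.0 * norm.sf(abs(z)))

    def __str__(self) -> str:
        sub = f" quintile {self.spec.subgroup}" if self.spec.subgroup else ""
        return (f"{self.spec.outcome}{sub} [{self.spec.weight_source}]: "
                f"HR {self.hr:.2g} (95% CI {self.ci_lower:.2g}-"
                f"{self.ci_upper:.2g}), {self.n_events} events / "
                f"{self.n_person_visits} person-visits")


def _outcome_rows(panel: CohortPanel, outcome: str) -> pd.DataFrame:
    """Risk-set rows for the chosen outcome.

    For death the panel rows already end at the event.  For (first) CVD the
    risk set ends at the first CVD event, so later rows are dropped.
    """
    df = panel.data
    if outcome == "death":
        return df
    # keep rows up to and including the first cvd event per patient
    g = df.groupby("patient_id", sort=False)["event_cvd"]
    had_prior = g.cumsum() - df["event_cvd"]
    return df[had_prior == 0]


def _merge_weights(rows: pd.DataFrame, weights: WeightSet | None,
                   source: str) -> np.ndarray:
    if source == "none" or weights is None:
        if source != "none":
            raise ConfigError(f"weight_source {source!r} but no weights given")
        return np.ones(len(rows))
    if source == "stabilized":
        col = "stabilized_weight"
        tab = weights.table
    elif source in ("truncated-95", "truncated-99"):
        pct = int(source.split("-")[1])
        if (weights.truncation_percentile != pct
                or "truncated_weight" not in weights.table.columns):
            weights = truncate_weights(weights, pct)
        col = "truncated_weight"
        tab = weights.table
    else:  # pragma: no cover - guarded by OutcomeModelSpec
        raise ConfigError(f"unknown weight source {source!r}")
    merged = rows[["patient_id", "visit"]].merge(
        tab[["patient_id", "visit", col]], on=["patient_id", "visit"],
        how="left", validate="one_to_one")
    w = merged[col].to_numpy()
    if np.any(~np.isfinite(w)):
        raise ConfigError(
            "weights are not aligned with the outcome rows "
            "(person-visits without a weight)"
        )
    return w


def _time_columns(month: np.ndarray, T: int, time_terms: str) -> tuple:
    m = month / T  # scaled to (0, 1] for conditioning
    if time_terms == "linear":
        return [m], ["month"]
    return [m, m ** 2, m ** 3], ["month", "month2", "month3"]


def fit_msm(panel: CohortPanel, weights: WeightSet | None,
            spec: OutcomeModelSpec,
            quintiles: pd.Series | None = None) -> EffectEstimate:
    """Fit the weighted pooled logistic outcome model.

    Returns the exponentiated current-treatment coefficient with a Wald 95%
    CI from the patient-clustered sandwich.  Scaling all weights by a
    positive constant leaves the point estimate unchanged.
    """
    sub_panel = panel
    if spec.subgroup is not None:
        if quintiles is None:
            quintiles = assign_ua_quintiles(panel)
        keep = quintiles.index[quintiles == spec.subgroup]
        sub_panel = panel.subset_patients(keep)
    rows = _outcome_rows(sub_panel, spec.outcome)
    event_col = "event_death" if spec.outcome == "death" else "event_cvd"
    y = rows[event_col].to_numpy(dtype=float)
    n_events = int(y.sum())
    if n_events == 0:
        raise ZeroEventsError(
            f"zero {spec.outcome} events in the analysis sample; for sparse "
            "subgroups use the reduced cubic polynomial-month specification"
        )
    w = _merge_weights(rows, weights, spec.weight_source)
    month = rows["visit"].to_numpy(dtype=float)
    tcols, tnames = _time_columns(month, panel.T, spec.time_terms)
    # degenerate designs (e.g. a single visit) make time columns constant
    # and collinear with the intercept; drop them rather than fail
    keep = [i for i, c in enumerate(tcols) if np.ptp(c) > 0]
    cols = [np.ones(len(rows))] + [tcols[i] for i in keep]
    names = ["intercept"] + [tnames[i] for i in keep]
    for cov in spec.adjust_baseline:
        cols.append(rows[cov].to_numpy(dtype=float))
        names.append(cov)
    cols.append(rows["treatment"].to_numpy(dtype=float))
    names.append("treatment")
    X = np.column_stack(cols)
    fit = fit_logistic(y, X, weights=w,
                       cluster_ids=rows["patient_id"].to_numpy(),
                       column_names=names)
    idx = names.index("treatment")
    return EffectEstimate(
        log_hr=float(fit.coefficients[idx]),
        robust_se=float(fit.bse_robust[idx]),
        n_events=n_events,
        n_person_visits=len(rows),
        spec=spec,
        model_fit=fit,
    )


def run_quintile_analysis(panel: CohortPanel, weights: WeightSet | None,
                          spec: OutcomeModelSpec,
                          quintiles: pd.Series | None = None) -> list:
    """One MSM fit per baseline-UA quintile (cubic month terms).

    Per-quintile failures (zero events, separation) are collected as the
    exception object in that slot rather than aborting the batch.
    """
    if quintiles is None:
        quintiles = assign_ua_quintiles(panel)
    out = []
    for q in range(1, 6):
        qspec = replace(spec, subgroup=q, time_terms="cubic")
        try:
            out.append(fit_msm(panel, weights, qspec, quintiles=quintiles))
        except EstimationError as exc:
            out.append(exc)
    return out


def sensitivity_truncation(panel: CohortPanel, weights: WeightSet,
                           spec: OutcomeModelSpec) -> dict:
    """The same fit under no truncation and 95th/99th-percentile truncation."""
    out = {}
    for label, source in (("none", "stabilized"),
                          ("95", "truncated-95"),
                          ("99", "truncated-99")):
        out[label] = fit_msm(panel, weights,
                             replace(spec, weight_source=source))
    return out


class MarginalStructuralModel:
    """Marginal structural model for a time-varying binary treatment.

    Parameters
    ----------
    panel : CohortPanel
        Long-format person-visit data; LOCF imputation is applied to the
        propensity labs on construction if any are missing.
    propensity : PropensitySpec
        Covariates of the treatment (denominator) model; the numerator model
        drops the time-dependent labs.
    outcome : OutcomeModelSpec
        The outcome model specification (outcome, time terms, weights).

    Examples
    --------
    >>> model = MarginalStructuralModel(panel)
    >>> res = model.fit(truncation=99)
    >>> print(res.summary())
    """

    def __init__(self, panel: CohortPanel,
                 propensity: PropensitySpec | None = None,
                 outcome: OutcomeModelSpec | None = None):
        self.propensity = propensity or PropensitySpec()
        self.outcome = outcome or OutcomeModelSpec()
        labs = [lab for lab in self.propensity.time_dependent
                if lab in panel.data.columns]
        if panel.data[labs].isna().any().any():
            panel = locf_impute(panel, labs)
        self.panel = panel
        self.quintiles = assign_ua_quintiles(panel)

    @classmethod
    def from_csv(cls, path, schema: dict | None = None, T: int = 36,
                 **kwargs) -> "MarginalStructuralModel":
        from .panel import read_panel
        return cls(read_panel(path, schema=schema, T=T), **kwargs)

    def compute_weights(self) -> WeightSet:
        den_fit, den_preds = fit_denominator_model(self.panel, self.propensity)
        num_fit, num_preds = fit_numerator_model(self.panel, self.propensity)
        ws = compute_stabilized_weights(self.panel, den_preds, num_preds)
        self._den_fit, self._num_fit = den_fit, num_fit
        return ws

    def fit(self, truncation: int | None = None) -> "MSMResults":
        """Fit weights and outcome model; returns an :class:`MSMResults`.

        ``truncation`` of 95 or 99 truncates the stabilized weights at the
        mirrored percentile bounds before the outcome fit; None uses the
        untruncated stabilized weights.
        """
        weights = self.compute_weights()
        if truncation is not None:
            weights = truncate_weights(weights, truncation)
            spec = replace(self.outcome,
                           weight_source=f"truncated-{truncation}")
        else:
            spec = replace(self.outcome, weight_source="stabilized")
        effect = fit_msm(self.panel, weights, spec, quintiles=self.quintiles)
        naive = fit_msm(self.panel, None,
                        replace(spec, weight_source="none"),
                        quintiles=self.quintiles)
        return MSMResults(
            model=self, effect=effect, naive=naive, weights=weights,
            diagnostics=weight_diagnostics(weights),
            denominator_fit=self._den_fit, numerator_fit=self._num_fit,
        )


@dataclass
class MSMResults:
    """Estimates, weights and diagnostics from a fitted MSM."""

    model: MarginalStructuralModel
    effect: EffectEstimate
    naive: EffectEstimate
    weights: WeightSet
    diagnostics: "object"
    denominator_fit: LogisticFit
    numerator_fit: LogisticFit

    def quintile_effects(self) -> list:
        return run_quintile_analysis(self.model.panel, self.weights,
                                     self.effect.spec,
                                     quintiles=self.model.quintiles)

    def truncation_sensitivity(self) -> dict:
        return sensitivity_truncation(self.model.panel, self.weights,
                                      self.effect.spec)

    def summary(self) -> str:
        d = self.diagnostics
        lines = [
            "Marginal structural model (discrete-time pooled logistic)",
            "=" * 60,
            f"outcome: {self.effect.spec.outcome}   "
            f"weights: {self.effect.spec.weight_source}   "
            f"time terms: {self.effect.spec.time_terms}",
            f"person-visits: {self.effect.n_person_visits}   "
            f"events: {self.effect.n_events}   "
            f"patients: {self.model.panel.n_patients}",
            "-" * 60,
            f"IPTW-weighted HR: {self.effect.hr:.2g} "
            f"(95% CI {self.effect.ci_lower:.2g}-{self.effect.ci_upper:.2g})",
            f"naive (unweighted) HR: {self.naive.hr:.2g} "
            f"(95% CI {self.naive.ci_lower:.2g}-{self.naive.ci_upper:.2g})",
            "-" * 60,
            str(d),
        ]
        return "\n".join(lines)
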