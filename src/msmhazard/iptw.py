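"""Inverse-probability-of-treatment weights for a time-varying treatment.

Two pooled logistic models are fitted over the stacked person-visit rows:

* the **denominator** model predicts this month's treatment from the previous
  month's treatment, baseline covariates and the previous month's labs;
* the **numerator** model is the same without the time-dependent labs.

Per visit the fitted probability is converted to the probability of the
treatment actually received (p if treated, 1-p if not); cumulative products
over a patient's visits give the numerator and 1/denominator, and their
product is the stabilized weight, whose mean is ~1 when the denominator
model is correct.  Truncation resets weights outside mirrored percentile
bounds to those bounds, trading a little bias for much variance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError, InfiniteWeightError, SchemaError
from .estimation import LogisticFit, fit_logistic
from .panel import CohortPanel

logger = logging.getLogger(__name__)

__all__ = [
    "PropensitySpec",
    "WeightSet",
    "WeightDiagnostics",
    "build_design",
    "fit_denominator_model",
    "fit_numerator_model",
    "compute_stabilized_weights",
    "truncate_weights",
    "weight_diagnostics",
]

#: fitted probabilities are clamped into this open interval before inversion
PRED_CLAMP = 1e-10


@dataclass
class PropensitySpec:
    """Covariate roster for the treatment-probability models.

    ``time_dependent`` labs enter as previous-visit (lag-1) values; at visit 1
    the baseline value stands in for the unavailable lag.  The previous
    treatment indicator is always included (at visit 1: treatment at
    baseline).
    """

    time_dependent: list = field(default_factory=lambda: ["ua", "alb"])
    baseline: list = field(default_factory=lambda: [
        "age", "sex_male", "bmi", "diabetes"])
    lag: int = 1
    include_previous_treatment: bool = True  # always true; kept explicit

    def __post_init__(self):
        if self.lag < 1:
            raise ConfigError("lag must be >= 1")
        if not self.include_previous_treatment:
            raise ConfigError("previous treatment must always be included")


def _lagged_columns(panel: CohortPanel, spec: PropensitySpec) -> pd.DataFrame:
    """Stacked design columns for every person-visit row of the panel."""
    df = panel.data
    for lab in spec.time_dependent:
        if lab not in df.columns:
            raise SchemaError(f"requested lab {lab!r} absent from panel")
    for cov in spec.baseline:
        if cov not in df.columns:
            raise SchemaError(f"baseline covariate {cov!r} absent from panel")
    g = df.groupby("patient_id", sort=False)
    out = pd.DataFrame(index=df.index)
    out["patient_id"] = df["patient_id"]
    out["visit"] = df["visit"]
    out["treatment"] = df["treatment"]
    prev = g["treatment"].shift(1)
    out["prev_treatment"] = prev.fillna(df["baseline_treatment"]).astype(float)
    for lab in spec.time_dependent:
        lagged = g[lab].shift(spec.lag)
        base_col = f"baseline_{lab}"
        if base_col in df.columns:
            fallback = df[base_col]
        else:  # no explicit baseline: the first observed visit stands in
            fallback = g[lab].transform("first")
        out[f"prev_{lab}"] = lagged.fillna(fallback)
    for cov in spec.baseline:
        out[cov] = df[cov]
    return out


def build_design(panel: CohortPanel, spec: PropensitySpec,
                 visit: int) -> pd.DataFrame:
    """Design rows for one visit: patients still at risk at that visit.

    Covariate values are taken from ``visit - lag``; the previous-treatment
    column from ``visit - 1`` (the baseline treatment when visit = 1).
    """
    if visit < 1:
        raise ConfigError(f"visit must be >= 1, got {visit}")
    full = _lagged_columns(panel, spec)
    return full[full["visit"] == visit].reset_index(drop=True)


def _design_matrix(cols: pd.DataFrame, names: list) -> tuple:
    X = np.column_stack([np.ones(len(cols))]
                        + [cols[c].to_numpy(dtype=float) for c in names])
    return X, ["intercept"] + list(names)


def _fit_propensity(panel: CohortPanel, spec: PropensitySpec,
                    time_dependent: bool) -> tuple:
    cols = _lagged_columns(panel, spec)
    if cols[[f"prev_{lab}" for lab in spec.time_dependent]].isna().any().any():
        raise SchemaError(
            "missing lagged lab values: run locf_impute before weighting"
        )
    names = ["prev_treatment"] + list(spec.baseline)
    if time_dependent:
        names += [f"prev_{lab}" for lab in spec.time_dependent]
    X, colnames = _design_matrix(cols, names)
    y = cols["treatment"].to_numpy(dtype=float)
    fit = fit_logistic(y, X, cluster_ids=cols["patient_id"].to_numpy(),
                       column_names=colnames)
    preds = pd.Series(fit.predict(X), index=cols.index)
    return fit, preds


def fit_denominator_model(panel: CohortPanel,
                          spec: PropensitySpec) -> tuple[LogisticFit, pd.Series]:
    """Pooled logistic fit of treatment on full history (labs included)."""
    return _fit_propensity(panel, spec, time_dependent=True)


def fit_numerator_model(panel: CohortPanel,
                        spec: PropensitySpec) -> tuple[LogisticFit, pd.Series]:
    """As the denominator model but without the time-dependent labs."""
    return _fit_propensity(panel, spec, time_dependent=False)


@dataclass
class WeightDiagnostics:
    mean: float
    sd: float
    min: float
    max: float
    percentile_95: float
    percentile_99: float
    n_person_visits: int

    def as_dict(self) -> dict:
        return {
            "mean": self.mean, "sd": self.sd, "min": self.min,
            "max": self.max, "percentile_95": self.percentile_95,
            "percentile_99": self.percentile_99,
            "n_person_visits": self.n_person_visits,
        }

    def __str__(self) -> str:
        return (f"stabilized weights over {self.n_person_visits} person-visits: "
                f"mean {self.mean:.3g}, SD {self.sd:.3g} "
                f"(min {self.min:.3g}, max {self.max:.3g}), "
                f"95% point {self.percentile_95:.3g}, "
                f"99% point {self.percentile_99:.3g}")


@dataclass
class WeightSet:
    """Per person-visit propensity predictions and cumulative weights.

    ``table`` columns: patient_id, visit, ps_pred_denominator,
    ps_pred_numerator, visit-level factors, cumulative products, the
    stabilized weight and (once truncation is applied) the truncated weight.
    """

    table: pd.DataFrame
    truncation_percentile: float | None = None
    truncation_bounds: tuple | None = None
    n_clamped: int = 0

    def weights(self, source: str = "stabilized") -> pd.Series:
        """Select a weight column: 'stabilized', 'truncated' or 'none'."""
        if source == "none":
            return pd.Series(np.ones(len(self.table)), index=self.table.index)
        if source == "stabilized":
            return self.table["stabilized_weight"]
        if source == "truncated":
            if self.truncation_percentile is None:
                raise ConfigError("weights have not been truncated")
            return self.table["truncated_weight"]
        raise ConfigError(f"unknown weight source {source!r}")

    def diagnostics(self, source: str = "stabilized") -> WeightDiagnostics:
        return weight_diagnostics(self, source=source)

    def to_csv(self, path) -> None:
        cols = ["patient_id", "visit", "ps_pred_denominator",
                "ps_pred_numerator", "stabilized_weight"]
        if "truncated_weight" in self.table.columns:
            cols.append("truncated_weight")
        self.table[cols].to_csv(path, index=False, float_format="%.10g")

    @staticmethod
    def from_csv(path) -> "WeightSet":
        df = pd.read_csv(path)
        need = {"patient_id", "visit", "stabilized_weight"}
        if not need.issubset(df.columns):
            raise SchemaError(
                f"weight table missing columns: {sorted(need - set(df.columns))}"
            )
        ws = WeightSet(table=df)
        if "truncated_weight" in df.columns and df["truncated_weight"].notna().all():
            ws.truncation_percentile = float("nan")  # bounds unknown from file
        return ws


def compute_stabilized_weights(panel: CohortPanel, denom_preds: pd.Series,
                               numer_preds: pd.Series) -> WeightSet:
    """Convert visit-level predictions into cumulative stabilized weights.

    Per visit the factor is ``1/p`` (denominator side) or ``p`` (numerator
    side) when treated, and ``1/(1-p)`` / ``(1-p)`` when untreated; factors
    are multiplied cumulatively within patient over visits 1..t, and
    ``stabilized_weight(t)`` is the product of the cumulative numerator and
    the cumulative inverse denominator.
    """
    df = panel.data
    if len(denom_preds) != len(df) or len(numer_preds) != len(df):
        raise ConfigError("predictions are not aligned with the panel rows")
    pd_den = np.asarray(denom_preds, dtype=float)
    pd_num = np.asarray(numer_preds, dtype=float)
    for name, arr in (("denominator", pd_den), ("numerator", pd_num)):
        if np.any((arr == 0.0) | (arr == 1.0)):
            raise InfiniteWeightError(
                f"{name} prediction of exactly 0 or 1 yields an infinite weight"
            )
    n_clamped = int(((pd_den < PRED_CLAMP) | (pd_den > 1 - PRED_CLAMP)
                     | (pd_num < PRED_CLAMP) | (pd_num > 1 - PRED_CLAMP)).sum())
    if n_clamped:
        logger.warning("clamped %d saturated propensity predictions", n_clamped)
    pd_den = np.clip(pd_den, PRED_CLAMP, 1 - PRED_CLAMP)
    pd_num = np.clip(pd_num, PRED_CLAMP, 1 - PRED_CLAMP)

    treated = df["treatment"].to_numpy() == 1
    p_den_received = np.where(treated, pd_den, 1.0 - pd_den)
    p_num_received = np.where(treated, pd_num, 1.0 - pd_num)

    tab = pd.DataFrame({
        "patient_id": df["patient_id"].to_numpy(),
        "visit": df["visit"].to_numpy(),
        "ps_pred_denominator": pd_den,
        "ps_pred_numerator": pd_num,
        "visit_weight_denominator": 1.0 / p_den_received,
        "visit_weight_numerator": p_num_received,
    })
    g = tab.groupby("patient_id", sort=False)
    tab["cumulative_denominator_inverse"] = (
        g["visit_weight_denominator"].cumprod())
    tab["cumulative_numerator"] = g["visit_weight_numerator"].cumprod()
    tab["stabilized_weight"] = (tab["cumulative_numerator"]
                                * tab["cumulative_denominator_inverse"])
    if not np.all(np.isfinite(tab["stabilized_weight"])):
        raise InfiniteWeightError("non-finite stabilized weight produced")
    return WeightSet(table=tab)


def truncate_weights(weights: WeightSet,
                     percentile: int | None) -> WeightSet:
    """Reset weights outside mirrored percentile bounds to the bounds.

    ``percentile`` 95 uses the (5th, 95th) percentiles of the pooled
    person-visit stabilized weights as (lower, upper); 99 uses (1st, 99th).
    ``None`` skips truncation (the truncated column equals the stabilized
    one).  Idempotent: re-truncating at the same percentile changes nothing.
    """
    tab = weights.table.copy()
    sw = tab["stabilized_weight"].to_numpy()
    if percentile is None:
        tab["truncated_weight"] = sw
        return WeightSet(table=tab, truncation_percentile=None,
                         truncation_bounds=(float(sw.min()), float(sw.max())),
                         n_clamped=weights.n_clamped)
    if percentile not in (95, 99):
        raise ConfigError(
            f"truncation percentile must be 95 or 99 (or None), got {percentile}"
        )
    # order statistics (not interpolated) so that truncation is idempotent:
    # re-truncating a truncated set at the same percentile changes nothing
    lower = float(np.percentile(sw, 100 - percentile, method="lower"))
    upper = float(np.percentile(sw, percentile, method="higher"))
    tab["truncated_weight"] = np.clip(sw, lower, upper)
    logger.info("truncated weights at the %dth percentile: bounds "
                "(%.4g, %.4g)", percentile, lower, upper)
    return WeightSet(table=tab, truncation_percentile=float(percentile),
                     truncation_bounds=(lower, upper),
                     n_clamped=weights.n_clamped)


def weight_diagnostics(weights: WeightSet,
                       source: str = "stabilized") -> WeightDiagnostics:
    """Summary statistics of the pooled person-visit weights."""
    w = weights.weights(source).to_numpy()
    if w.size == 0:
        raise ConfigError("empty weight set")
    diag = WeightDiagnostics(
        mean=float(w.mean()),
        sd=float(w.std(ddof=1)) if w.size > 1 else 0.0,
        min=float(w.min()),
        max=float(w.max()),
        percentile_95=float(np.percentile(w, 95)),
        percentile_99=float(np.percentile(w, 99)),
        n_person_visits=int(w.size),
    )
    logger.info("%s", diag)
    return diag
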