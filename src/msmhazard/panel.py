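"""Long-format person-visit panel: data model, CSV I/O, LOCF, quintiles.

The single currency of the pipeline is the :class:`CohortPanel`, a validated
wrapper around a long-format :class:`pandas.DataFrame` with one row per
patient per monthly visit.  Baseline covariates are repeated on every row of
a patient; time-varying labs may be missing (NaN) until LOCF imputation.

Column conventions
------------------
required : patient_id, visit, treatment, event_death, event_cvd, censored
baseline : age, sex_male, bmi, diabetes, hd_vintage, baseline_treatment,
           baseline_ua (plus optional ``baseline_<lab>`` columns)
labs     : any subset of ``ua, alb, npcr, cgr, ferritin, na, ktv`` (open roster)
comorbid : any column prefixed ``cm_`` is treated as a binary baseline flag
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import PanelValidationError, SchemaError

logger = logging.getLogger(__name__)

__all__ = [
    "CohortPanel",
    "read_panel",
    "write_panel",
    "locf_impute",
    "assign_ua_quintiles",
    "REQUIRED_COLUMNS",
    "BASELINE_COLUMNS",
    "KNOWN_LABS",
]

REQUIRED_COLUMNS = [
    "patient_id", "visit", "treatment", "event_death", "event_cvd", "censored",
]
BASELINE_COLUMNS = [
    "age", "sex_male", "bmi", "diabetes", "hd_vintage",
    "baseline_treatment", "baseline_ua",
]
#: the time-varying serological / dialysis-adequacy markers we know about
KNOWN_LABS = ["ua", "alb", "npcr", "cgr", "ferritin", "na", "ktv"]

_BINARY_COLUMNS = ["treatment", "event_death", "event_cvd", "censored"]


@dataclass
class CohortPanel:
    """A validated long-format person-visit table.

    Parameters
    ----------
    data : DataFrame in the column convention above, one row per
        patient-visit, rows ending at the first death/censoring visit.
    T : the maximum visit index of the study design (default 36 months).
    """

    data: pd.DataFrame
    T: int = 36
    validate: bool = True
    dropped_patients: dict = field(default_factory=dict)

    def __post_init__(self):
        df = self.data
        missing = [c for c in REQUIRED_COLUMNS + BASELINE_COLUMNS
                   if c not in df.columns]
        if missing:
            raise SchemaError(f"panel is missing required columns: {missing}")
        df = df.sort_values(["patient_id", "visit"], kind="stable")
        df = df.reset_index(drop=True)
        self.data = df
        if self.validate:
            self._validate()

    # -- structure ---------------------------------------------------------
    def _validate(self) -> None:
        df = self.data
        for col in _BINARY_COLUMNS:
            vals = df[col].dropna().unique()
            if not np.isin(vals, [0, 1]).all():
                raise PanelValidationError(
                    f"column {col!r} must be binary 0/1; saw {sorted(vals)[:5]}"
                )
        both = (df["event_death"] == 1) & (df["censored"] == 1)
        if both.any():
            pid = df.loc[both, "patient_id"].iloc[0]
            raise PanelValidationError(
                f"patient {pid!r}: death and censoring flagged at the same visit"
            )
        grouped = df.groupby("patient_id", sort=False)
        visits = grouped["visit"]
        first = visits.first()
        bad = first[first != 1]
        if len(bad):
            raise PanelValidationError(
                f"patient {bad.index[0]!r}: visits must start at 1 "
                f"(first visit is {int(bad.iloc[0])})"
            )
        # consecutive: count == max visit index
        count = visits.count()
        last = visits.max()
        gap = count != last
        if gap.any():
            pid = count.index[gap][0]
            raise PanelValidationError(
                f"patient {pid!r}: non-consecutive visit indices"
            )
        if (last > self.T).any():
            pid = last.index[last > self.T][0]
            raise PanelValidationError(
                f"patient {pid!r}: visit index exceeds T={self.T}"
            )
        # rows stop at first event/censoring
        ended = grouped.apply(
            lambda g: bool(((g["event_death"] == 1) | (g["censored"] == 1))
                           .iloc[:-1].any()),
            include_groups=False,
        )
        if ended.any():
            pid = ended.index[ended][0]
            raise PanelValidationError(
                f"patient {pid!r}: rows continue past death/censoring"
            )
        # baseline covariates constant within patient
        for col in ["age", "baseline_ua", "baseline_treatment"]:
            if grouped[col].nunique(dropna=False).gt(1).any():
                raise PanelValidationError(
                    f"baseline column {col!r} varies within a patient"
                )

    # -- views -------------------------------------------------------------
    @property
    def n_patients(self) -> int:
        return self.data["patient_id"].nunique()

    @property
    def n_rows(self) -> int:
        return len(self.data)

    @property
    def lab_names(self) -> list:
        return [c for c in KNOWN_LABS if c in self.data.columns]

    @property
    def comorbidity_flags(self) -> list:
        return [c for c in self.data.columns if c.startswith("cm_")]

    @property
    def baselines(self) -> pd.DataFrame:
        """One row per patient: baseline covariates and comorbidity flags."""
        cols = (["patient_id"] + BASELINE_COLUMNS
                + [c for c in self.data.columns
                   if c.startswith(("baseline_", "cm_"))
                   and c not in BASELINE_COLUMNS])
        cols = list(dict.fromkeys(cols))
        return (self.data[cols].groupby("patient_id", sort=True)
                .first().reset_index())

    @property
    def visits(self) -> pd.DataFrame:
        """The person-visit rows (the full long table)."""
        return self.data

    def survival_table(self) -> pd.DataFrame:
        """One row per patient: follow-up time and death indicator.

        Patients alive and uncensored at their last visit are treated as
        censored there (administrative end of study).
        """
        g = self.data.groupby("patient_id", sort=True)
        out = pd.DataFrame({
            "patient_id": g.size().index,
            "time": g["visit"].max().to_numpy(),
            "event_death": g["event_death"].max().to_numpy().astype(int),
            "event_cvd": g["event_cvd"].max().to_numpy().astype(int),
        })
        return out

    def subset_patients(self, patient_ids) -> "CohortPanel":
        keep = self.data["patient_id"].isin(set(patient_ids))
        return CohortPanel(self.data.loc[keep].copy(), T=self.T, validate=False)

    def equals(self, other: "CohortPanel") -> bool:
        a = self.data.reset_index(drop=True)
        b = other.data.reset_index(drop=True)
        if list(a.columns) != list(b.columns):
            return False
        return a.equals(b)


def _ordered_columns(df: pd.DataFrame) -> list:
    lead = REQUIRED_COLUMNS + BASELINE_COLUMNS
    baseline_extra = sorted(c for c in df.columns
                            if c.startswith("baseline_") and c not in lead)
    cm = sorted(c for c in df.columns if c.startswith("cm_"))
    labs = [c for c in KNOWN_LABS if c in df.columns]
    other = [c for c in df.columns
             if c not in lead + baseline_extra + cm + labs]
    return lead + baseline_extra + cm + labs + sorted(other)


def read_panel(path, schema: dict | None = None, T: int = 36) -> CohortPanel:
    """Read a person-visit CSV into a validated CohortPanel.

    ``schema`` maps file column names to the canonical names above, e.g.
    ``{"id": "patient_id", "month": "visit"}``.  Missing lab values are empty
    fields in the CSV and become NaN.
    """
    df = pd.read_csv(path)
    if schema:
        df = df.rename(columns=dict(schema))
    missing = [c for c in REQUIRED_COLUMNS + BASELINE_COLUMNS
               if c not in df.columns]
    if missing:
        raise SchemaError(
            f"input file {path} is missing required columns: {missing}"
        )
    panel = CohortPanel(df, T=T)
    logger.info("read_panel: %d rows, %d patients from %s",
                panel.n_rows, panel.n_patients, path)
    return panel


def write_panel(panel: CohortPanel, path) -> None:
    """Write a panel as CSV with deterministic row and column order."""
    df = panel.data
    df = df[_ordered_columns(df)].sort_values(
        ["patient_id", "visit"], kind="stable")
    df.to_csv(path, index=False, float_format="%.10g")


def locf_impute(panel: CohortPanel, lab_names=None) -> CohortPanel:
    """Last observation carried forward, per patient, for the named labs.

    Leading missing values are back-filled from the first observed value so
    that every retained row is complete.  Patients for whom a named lab is
    never observed are dropped and recorded in ``dropped_patients``.
    Idempotent: applying it twice equals applying it once.
    """
    if lab_names is None:
        lab_names = panel.lab_names
    absent = [lab for lab in lab_names if lab not in panel.data.columns]
    if absent:
        raise SchemaError(f"labs not present in panel: {absent}")

    df = panel.data.copy()
    g = df.groupby("patient_id", sort=False)
    never = pd.Series(False, index=df["patient_id"].unique())
    for lab in lab_names:
        observed = g[lab].transform(lambda s: s.notna().any())
        never |= ~observed.groupby(df["patient_id"]).first()
    dropped = {pid: "lab never observed" for pid in never.index[never]}
    if dropped:
        logger.info("locf_impute: dropping %d patients with a never-observed "
                    "lab: %s", len(dropped), sorted(dropped)[:10])
        df = df[~df["patient_id"].isin(dropped)].copy()
        g = df.groupby("patient_id", sort=False)
    for lab in lab_names:
        df[lab] = g[lab].ffill()
        df[lab] = df.groupby("patient_id", sort=False)[lab].bfill()
    out = CohortPanel(df, T=panel.T, validate=False)
    out.dropped_patients = {**panel.dropped_patients, **dropped}
    return out


def assign_ua_quintiles(panel: CohortPanel) -> pd.Series:
    """Map patient_id -> quintile 1..5 of baseline serum uric acid.

    Quintile 1 is the lowest-UA fifth.  Ranks break ties by patient_id, then
    every patient sharing a boundary UA value is pulled down to the lower
    quintile, so the assignment is deterministic and a function of the UA
    value alone.  Invariant under strictly increasing transforms of UA.
    """
    base = panel.baselines[["patient_id", "baseline_ua"]]
    n = len(base)
    if n < 5:
        raise PanelValidationError(
            f"quintile stratification needs at least 5 patients, got {n}"
        )
    if base["baseline_ua"].isna().any():
        bad = base.loc[base["baseline_ua"].isna(), "patient_id"].iloc[0]
        raise PanelValidationError(f"patient {bad!r} has no baseline UA")
    ordered = base.sort_values(["baseline_ua", "patient_id"],
                               kind="stable").reset_index(drop=True)
    provisional = np.floor(5 * np.arange(n) / n).astype(int) + 1
    ordered["quintile"] = provisional
    # ties keep the lower quintile: collapse each distinct UA value to the
    # minimum provisional quintile within it
    ordered["quintile"] = ordered.groupby("baseline_ua")["quintile"].transform("min")
    return ordered.set_index("patient_id")["quintile"]
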