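"""Core data containers for psoriasis treatment cohorts.

A cohort is held as two pandas tables:

``patients``
    wide table, one row per patient (index = integer patient id), holding the
    assigned therapy, the baseline IGA severity stage (coded 0-3), and the
    enrollment covariates.  Missing covariate values are ``NaN``.
``visits``
    long table of follow-up visits with columns ``id``, ``day`` (days since
    enrollment, > 0) and ``iga`` (raw IGA score 0-4).

The four severity stages collapse the 5-point Investigator's Global
Assessment: IGA 0 and 1 form one stage, IGA 2, 3 and 4 each their own.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Severity stage labels, ordered from clear/almost-clear to severe.
STAGE_LABELS = ("IGA01", "IGA2", "IGA3", "IGA4")
N_STAGES = len(STAGE_LABELS)

#: The three treatment arms.  "traditional" = topical/phototherapy,
#: "systemic" = nonbiologic systemic drugs, "biologic" = biologic agents.
THERAPIES = ("traditional", "systemic", "biologic")

#: Follow-up windows in days since enrollment, half-open (lo, hi].
DEFAULT_WINDOWS = {"w1": (0, 30), "w2": (30, 365)}

CONTINUOUS_COVARIATES = ("age", "bmi", "duration", "pasi", "bsa", "dlqi")

#: Binary covariates, coded 0/1:
#: sex (1 = female), marital (1 = married), employment (1 = full time),
#: education (1 = college degree or higher), smoking (1 = current smoker),
#: family_history / nail / scalp / palmoplantar / genital / comorbidity
#: (1 = positive / affected).
BINARY_COVARIATES = (
    "sex", "marital", "employment", "education", "smoking",
    "family_history", "nail", "scalp", "palmoplantar", "genital",
    "comorbidity",
)

COVARIATES = CONTINUOUS_COVARIATES + BINARY_COVARIATES

#: Variables entering the Mahalanobis metric.  BMI is recorded at enrollment
#: but is not part of the matching variable set; the baseline stage enters as
#: an ordinal 0-3 code.
MATCHING_COVARIATES = tuple(c for c in COVARIATES if c != "bmi") + ("baseline_stage",)

COVARIATE_BOUNDS = {
    "pasi": (0.0, 72.0),
    "bsa": (0.0, 100.0),
    "dlqi": (0.0, 30.0),
    "age": (0.0, 120.0),
    "duration": (0.0, 100.0),
    "bmi": (8.0, 80.0),
}

PATIENT_COLUMNS = ("therapy", "baseline_stage") + COVARIATES
VISIT_COLUMNS = ("id", "day", "iga")


class CohortError(ValueError):
    """Raised when a cohort table violates its structural invariants."""


@dataclass
class PatientRecord:
    """One patient: baseline data plus the ordered follow-up visit list."""

    id: int
    therapy: str
    baseline_stage: int
    covariates: dict
    visits: list  # list of (day, iga) tuples, days strictly increasing

    def __post_init__(self):
        if self.therapy not in THERAPIES:
            raise CohortError(f"unknown therapy {self.therapy!r}")
        if self.baseline_stage not in range(N_STAGES):
            raise CohortError(f"baseline_stage must be 0..3, got {self.baseline_stage}")
        days = [d for d, _ in self.visits]
        if any(d <= 0 for d in days) or any(b <= a for a, b in zip(days, days[1:])):
            raise CohortError("visit days must be positive and strictly increasing")


@dataclass
class CohortTable:
    """A cohort: wide per-patient baseline table + long visit table."""

    patients: pd.DataFrame
    visits: pd.DataFrame

    @property
    def n(self) -> int:
        return len(self.patients)

    def therapy_counts(self) -> pd.Series:
        return self.patients["therapy"].value_counts()

    def copy(self) -> "CohortTable":
        return CohortTable(self.patients.copy(), self.visits.copy())

    def patient_record(self, pid: int) -> PatientRecord:
        row = self.patients.loc[pid]
        vis = self.visits[self.visits["id"] == pid].sort_values("day")
        return PatientRecord(
            id=int(pid),
            therapy=row["therapy"],
            baseline_stage=int(row["baseline_stage"]),
            covariates={c: row[c] for c in COVARIATES},
            visits=list(zip(vis["day"].astype(int), vis["iga"].astype(int))),
        )

    def validate(self) -> "CohortTable":
        """Check structural invariants; return self on success."""
        missing_cols = set(PATIENT_COLUMNS) - set(self.patients.columns)
        if missing_cols:
            raise CohortError(f"patients table lacks columns {sorted(missing_cols)}")
        if list(self.visits.columns[:3]) != list(VISIT_COLUMNS):
            raise CohortError(f"visits table must have columns {VISIT_COLUMNS}")
        if not self.patients.index.is_unique:
            raise CohortError("patient ids must be unique")
        bad = ~self.patients["therapy"].isin(THERAPIES)
        if bad.any():
            raise CohortError(f"unknown therapy values: {self.patients.loc[bad, 'therapy'].unique()}")
        stage = self.patients["baseline_stage"]
        if stage.isna().any():
            raise CohortError("baseline_stage may never be missing")
        if not stage.isin(range(N_STAGES)).all():
            raise CohortError("baseline_stage codes must be in 0..3")
        if len(self.visits):
            if (self.visits["day"] <= 0).any():
                raise CohortError("visit days must be > 0")
            if not self.visits["iga"].isin(range(5)).all():
                raise CohortError("visit IGA scores must be integers 0..4")
            d = self.visits.sort_values(["id", "day"], kind="mergesort")
            same = d["id"].values[1:] == d["id"].values[:-1]
            if ((d["day"].values[1:] <= d["day"].values[:-1]) & same).any():
                raise CohortError("visit days must be strictly increasing per patient")
            unknown = set(self.visits["id"]) - set(self.patients.index)
            if unknown:
                raise CohortError(f"visits reference unknown patients: {sorted(unknown)[:5]}")
        for var, (lo, hi) in COVARIATE_BOUNDS.items():
            vals = self.patients[var].dropna()
            if ((vals < lo) | (vals > hi)).any():
                raise CohortError(f"{var} out of bounds [{lo}, {hi}]")
        return self


def stage_of_iga(score: int) -> int:
    """Collapse a raw IGA score 0-4 into a severity stage code 0-3.

    IGA 0 and 1 (clear / almost clear) form one stage; 2, 3 and 4 map to
    their own stages.
    """
    if score not in (0, 1, 2, 3, 4):
        raise ValueError(f"IGA score must be an integer 0..4, got {score!r}")
    return 0 if score <= 1 else score - 1
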