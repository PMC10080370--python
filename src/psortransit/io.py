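"""Plain-text serialization of cohorts and derived tables.

A cohort on disk is a pair of CSV files: ``patients.csv`` (wide, one row per
patient, empty cell = missing) and ``visits.csv`` (long: id, day, iga).
Output is deterministic — fixed column order, fixed float formatting — so
identical cohorts produce byte-identical files.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import CohortTable, PATIENT_COLUMNS, VISIT_COLUMNS

PATIENTS_FILE = "patients.csv"
VISITS_FILE = "visits.csv"
TRUTH_FILE = "truth.json"


def write_cohort(cohort: CohortTable, out_dir) -> Path:
    """Write patients.csv and visits.csv under ``out_dir``; return the dir."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    patients = cohort.patients[list(PATIENT_COLUMNS)].sort_index()
    patients.to_csv(out_dir / PATIENTS_FILE, index_label="id",
                    float_format="%.10g", lineterminator="\n")
    visits = cohort.visits[list(VISIT_COLUMNS)].sort_values(
        ["id", "day"], kind="mergesort")
    visits.to_csv(out_dir / VISITS_FILE, index=False, lineterminator="\n")
    return out_dir


def read_cohort(in_dir) -> CohortTable:
    in_dir = Path(in_dir)
    patients = pd.read_csv(in_dir / PATIENTS_FILE, index_col="id")
    patients["baseline_stage"] = patients["baseline_stage"].astype(int)
    visits = pd.read_csv(in_dir / VISITS_FILE)
    visits = visits.astype({"id": np.int64, "day": np.int64, "iga": np.int64})
    return CohortTable(patients, visits).validate()
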