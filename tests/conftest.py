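"""Shared fixtures: small synthetic cohorts and hand-built micro-cohorts."""

import numpy as np
import pandas as pd
import pytest

from psortransit.cohort import COVARIATES, CohortTable, PATIENT_COLUMNS
from psortransit.simulate import TruthParameters, generate_cohort


def make_patients(rows: list[dict]) -> pd.DataFrame:
    """Build a patients table from dicts; unspecified covariates get benign
    defaults so micro-cohorts stay terse."""
    defaults = {"age": 40.0, "bmi": 24.0, "duration": 5.0, "pasi": 10.0,
                "bsa": 15.0, "dlqi": 8.0}
    defaults.update({c: 0.0 for c in COVARIATES if c not in defaults})
    out = []
    for i, row in enumerate(rows):
        rec = {"therapy": "traditional", "baseline_stage": 2, **defaults}
        rec.update(row)
        rec["_id"] = row.get("id", i)
        out.append(rec)
    frame = pd.DataFrame(out).set_index("_id")
    frame.index.name = "id"
    return frame[list(PATIENT_COLUMNS)]


def make_cohort(rows: list[dict], visits: list[tuple] = ()) -> CohortTable:
    """visits: iterable of (id, day, iga)."""
    patients = make_patients(rows)
    vis = pd.DataFrame(list(visits), columns=["id", "day", "iga"]) if visits \
        else pd.DataFrame(columns=["id", "day", "iga"]).astype(int)
    return CohortTable(patients, vis).validate()


@pytest.fixture(scope="session")
def default_params() -> TruthParameters:
    return TruthParameters(n=1500, seed=11)


@pytest.fixture(scope="session")
def small_cohort(default_params):
    """Complete confounded cohort, n=1500, no missingness applied."""
    cohort, _ = generate_cohort(default_params)
    return cohort


@pytest.fixture
def tri_cohort():
    """Three patients, one per therapy."""
    return make_cohort([
        {"id": 1, "therapy": "traditional", "pasi": 5.0},
        {"id": 2, "therapy": "systemic", "pasi": 12.0},
        {"id": 3, "therapy": "biologic", "pasi": 20.0},
    ])


def random_mini_cohort(rng: np.random.Generator, n_max: int = 30) -> CohortTable:
    """Random small cohort with all three arms represented."""
    n = int(rng.integers(6, n_max + 1))
    therapies = ["traditional", "systemic", "biologic"]
    rows = []
    for i in range(n):
        therapy = therapies[i % 3] if i < 3 else therapies[rng.integers(3)]
        rows.append({
            "id": i, "therapy": therapy,
            "baseline_stage": int(rng.integers(4)),
            "age": float(rng.uniform(18, 80)),
            "bmi": float(rng.uniform(18, 35)),
            "duration": float(rng.uniform(0, 30)),
            "pasi": float(rng.uniform(0, 40)),
            "bsa": float(rng.uniform(0, 80)),
            "dlqi": float(rng.integers(0, 31)),
            **{c: float(rng.integers(2)) for c in
               ("sex", "marital", "employment", "education", "smoking",
                "family_history", "nail", "scalp", "palmoplantar", "genital",
                "comorbidity")},
        })
    return make_cohort(rows)
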