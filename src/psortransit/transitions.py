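"""Window outcomes and per-therapy transition matrix estimation.

Each patient's outcome in a follow-up window is the severity stage of the
*last* visit inside that window.  Patients with no visit in a window are
handled by last observation carried forward: the first window carries the
baseline stage, the second window carries the first window's outcome
(which may itself be the carried baseline).  LOCF makes every outcome
defined, so transition rows always have full denominators.

A transition estimate for therapy T on a matched cohort takes each triple's
T-slot unit with frequency weights — the matched pseudo-population, with
exactly one representative per triple, so the three per-therapy populations
have identical size and, by construction, comparable covariates.  The
``overall`` population pools the three.  Cell variances are binomial,
p(1-p)/n_row, with the weighted row denominator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import (
    CohortTable,
    DEFAULT_WINDOWS,
    N_STAGES,
    PatientRecord,
    THERAPIES,
    stage_of_iga,
)
from .match import MatchedCohort, _SLOT

POPULATIONS = THERAPIES + ("overall",)

OBSERVED = "observed"
LOCF_FROM_W1 = "locf_from_w1"
LOCF_FROM_BASELINE = "locf_from_baseline"


@dataclass
class WindowOutcome:
    patient_id: int
    window: str
    stage: int
    source: str


@dataclass
class TransitionEstimate:
    """4x4 transition probabilities with per-cell binomial variances."""

    therapy: str  # one of THERAPIES or "overall"
    window: str
    p: np.ndarray       # (4, 4); rows with n_row == 0 are NaN
    var: np.ndarray     # (4, 4)
    n_row: np.ndarray   # (4,) weighted row denominators

    @property
    def undefined_rows(self) -> list:
        return [int(i) for i in np.flatnonzero(self.n_row == 0)]

    def validate(self) -> "TransitionEstimate":
        defined = self.n_row > 0
        if defined.any():
            sums = self.p[defined].sum(axis=1)
            if np.abs(sums - 1.0).max() > 1e-9:
                raise ValueError("defined rows must sum to 1 within 1e-9")
            if (self.var[defined] < 0).any():
                raise ValueError("variances must be nonnegative")
        return self


def bin_iga(score: int) -> int:
    """Collapse a raw IGA score into a severity stage code (0-3)."""
    return stage_of_iga(score)


def window_outcome(patient: PatientRecord, window: str,
                   windows: dict = DEFAULT_WINDOWS) -> WindowOutcome:
    """Outcome stage of one patient in one window, LOCF if unobserved."""
    lo, hi = windows[window]
    in_window = [(d, iga) for d, iga in patient.visits if lo < d <= hi]
    if in_window:
        return WindowOutcome(patient.id, window, bin_iga(in_window[-1][1]), OBSERVED)
    if window == "w1" or "w1" not in windows:
        return WindowOutcome(patient.id, window, patient.baseline_stage,
                             LOCF_FROM_BASELINE)
    prev = window_outcome(patient, "w1", windows)
    source = LOCF_FROM_W1 if prev.source == OBSERVED else LOCF_FROM_BASELINE
    return WindowOutcome(patient.id, window, prev.stage, source)


def cohort_outcomes(cohort: CohortTable,
                    windows: dict = DEFAULT_WINDOWS) -> pd.DataFrame:
    """Per-patient outcome stage and source for every window (vectorized)."""
    out = pd.DataFrame(index=cohort.patients.index)
    out["baseline_stage"] = cohort.patients["baseline_stage"]
    visits = cohort.visits
    prev_stage = out["baseline_stage"]
    prev_observed = pd.Series(False, index=out.index)
    for window, (lo, hi) in windows.items():
        vw = visits[(visits["day"] > lo) & (visits["day"] <= hi)]
        last = vw.sort_values(["id", "day"], kind="mergesort").groupby("id").tail(1)
        stage = pd.Series(
            [bin_iga(int(s)) for s in last["iga"]], index=last["id"].to_numpy())
        observed = out.index.isin(stage.index)
        filled = stage.reindex(out.index)
        filled[~observed] = prev_stage[~observed]
        source = np.where(
            observed, OBSERVED,
            np.where(prev_observed, LOCF_FROM_W1, LOCF_FROM_BASELINE))
        out[f"{window}_stage"] = filled.astype(int)
        out[f"{window}_source"] = source
        prev_stage = out[f"{window}_stage"]
        prev_observed = pd.Series(observed | prev_observed.to_numpy(), index=out.index)
    return out


def _units_and_weights(matched: MatchedCohort, therapy: str):
    if therapy == "overall":
        ids = pd.concat([matched.triples[_SLOT[t]] for t in THERAPIES])
    else:
        ids = matched.triples[_SLOT[therapy]]
    w = ids.value_counts().sort_index()
    return w.index.to_numpy(), w.to_numpy(dtype=float)


def _crosstab(baseline: np.ndarray, outcome: np.ndarray,
              weights: np.ndarray) -> np.ndarray:
    counts = np.zeros((N_STAGES, N_STAGES))
    np.add.at(counts, (baseline, outcome), weights)
    return counts


def _estimate_from_counts(counts: np.ndarray, therapy: str,
                          window: str) -> TransitionEstimate:
    n_row = counts.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = counts / n_row[:, None]
    var = np.where(np.isnan(p), np.nan, 0.0)
    defined = n_row > 0
    pv = p[defined]
    var[defined] = pv * (1.0 - pv) / n_row[defined, None]
    var[defined] = np.where((pv == 0.0) | (pv == 1.0), 0.0, var[defined])
    return TransitionEstimate(therapy, window, p, var, n_row).validate()


def estimate_transitions(cohort: CohortTable, matched: MatchedCohort | None,
                         therapy: str, window: str,
                         windows: dict = DEFAULT_WINDOWS) -> TransitionEstimate:
    """Estimate the 4x4 transition matrix for one population and window.

    With ``matched=None`` the naive (unmatched, unweighted) estimate on the
    raw therapy arm is returned; ``therapy="overall"`` then uses the whole
    cohort.  Rows with zero denominator are reported as undefined (NaN),
    never silently zeroed.
    """
    if therapy not in POPULATIONS:
        raise ValueError(f"therapy must be one of {POPULATIONS}, got {therapy!r}")
    if window not in windows:
        raise ValueError(f"unknown window {window!r}")
    outcomes = cohort_outcomes(cohort, windows)
    if matched is None:
        if therapy == "overall":
            sel = outcomes
        else:
            sel = outcomes[cohort.patients["therapy"] == therapy]
        ids = sel.index.to_numpy()
        weights = np.ones(len(ids))
    else:
        matched.validate(cohort)
        ids, weights = _units_and_weights(matched, therapy)
    baseline = outcomes.loc[ids, "baseline_stage"].to_numpy()
    outcome = outcomes.loc[ids, f"{window}_stage"].to_numpy()
    counts = _crosstab(baseline, outcome, weights)
    return _estimate_from_counts(counts, therapy, window)
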