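"""Synthetic cohort generator with known ground truth.

The generator emulates the statistical structure of a dermatology registry
cohort treated with one of three therapies (traditional, systemic, biologic):

* enrollment covariates whose marginals match the published cohort, with a
  shared latent severity factor inducing realistic correlation between PASI,
  BSA, DLQI, disease duration, lesion sites and the baseline IGA stage;
* confounded treatment assignment — a multinomial-logistic model in which
  more severe patients (higher PASI/DLQI, longer duration, worse stage) are
  more likely to receive biologics, with intercepts calibrated so the
  marginal arm shares hit configurable targets;
* therapy- and window-specific latent transition kernels: every follow-up
  visit's severity stage is drawn from the kernel row of the patient's
  baseline stage, optionally tilted toward worse outcomes for patients with
  above-average severity (residual confounding beyond the baseline stage);
* visit schedules inside two follow-up windows, 0-1 month and 1-12 months;
* missing-at-random masking of covariates and of whole follow-up windows,
  with masking probabilities driven only by the (never-masked) baseline
  stage, normalized to hit configured marginal rates.

Every draw flows through one ``numpy.random.Generator`` seeded from
``TruthParameters.seed``, so identical parameters give identical cohorts.
"""

from __future__ import annotations

import copy as _copy
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import ndtri

from . import reference
from .cohort import (
    BINARY_COVARIATES,
    COVARIATES,
    CohortTable,
    N_STAGES,
    PATIENT_COLUMNS,
    THERAPIES,
    DEFAULT_WINDOWS,
)

_STAGE_TO_SCORE = {0: None, 1: 2, 2: 3, 3: 4}  # stage 0 draws IGA 0 or 1

#: Marginal probabilities for the binary covariates (cohort-wide).
_BINARY_PROBS = {
    "sex": 0.336, "marital": 0.74, "employment": 0.58, "education": 0.30,
    "smoking": 0.255, "family_history": 0.16, "nail": 0.235, "scalp": 0.665,
    "palmoplantar": 0.19, "genital": 0.13, "comorbidity": 0.15,
}

#: Loading of each binary covariate on the latent severity factor (logit scale).
_BINARY_SEVERITY_LOADING = {
    "nail": 0.15, "scalp": 0.10, "palmoplantar": 0.15, "genital": 0.12,
    "family_history": 0.05,
}

_DEFAULT_ASSIGNMENT_COEFS = {
    "traditional": {"pasi": 0.0, "dlqi": 0.0, "duration": 0.0, "stage": 0.0, "intercept": 0.0},
    "systemic": {"pasi": 0.25, "dlqi": 0.05, "duration": 0.05, "stage": 0.15, "intercept": 0.0},
    "biologic": {"pasi": 0.55, "dlqi": 0.25, "duration": 0.35, "stage": 0.25, "intercept": 0.0},
}

#: Per-covariate masking rates, all inside the published 1.5%-8.1% range.
_DEFAULT_COVARIATE_MISSING_RATES = {
    "age": 0.015, "bmi": 0.058, "duration": 0.065, "pasi": 0.060,
    "bsa": 0.055, "dlqi": 0.075, "sex": 0.015, "marital": 0.032,
    "employment": 0.045, "education": 0.052, "smoking": 0.038,
    "family_history": 0.081, "nail": 0.025, "scalp": 0.020,
    "palmoplantar": 0.030, "genital": 0.070, "comorbidity": 0.040,
}


def _default_kernels():
    """Row-renormalized published per-therapy matrices as latent kernels."""
    kernels = {}
    for therapy in THERAPIES:
        kernels[therapy] = {}
        for window in ("w1", "w2"):
            m = reference.transition_matrix(therapy, window)
            kernels[therapy][window] = (m / m.sum(axis=1, keepdims=True)).tolist()
    return kernels


class TruthError(ValueError):
    """Raised for invalid ground-truth parameters."""


@dataclass
class TruthParameters:
    """Ground truth driving one synthetic cohort.

    Attributes
    ----------
    n : cohort size (>= 10).
    seed : master seed for all randomness.
    baseline_stage_probs : marginal distribution of the 4 baseline stages.
    target_shares : marginal therapy shares the assignment intercepts are
        calibrated to; ``None`` disables calibration (raw intercepts used).
    assignment_coefs : per-therapy multinomial-logit coefficients on
        standardized log-PASI, DLQI, log-duration and the centred stage code.
    kernels : ``kernels[therapy][window]`` 4x4 row-stochastic matrix of
        baseline-stage to window-outcome transition probabilities.
    outcome_tilt : strength of the residual severity effect on outcomes; 0
        makes outcomes depend on (therapy, baseline stage) only.
    covariate_missing_rates : marginal masking rate per covariate.
    visit_missing_rates : per-window probability that a patient has no
        visit record in that window.
    windows : follow-up windows in days, half-open (lo, hi].
    """

    n: int = reference.REPORTED_N
    seed: int = 20201
    baseline_stage_probs: tuple = (0.15, 0.30, 0.35, 0.20)
    target_shares: dict | None = field(
        default_factory=lambda: dict(reference.REPORTED_ARM_SHARES))
    assignment_coefs: dict = field(
        default_factory=lambda: _copy.deepcopy(_DEFAULT_ASSIGNMENT_COEFS))
    kernels: dict = field(default_factory=_default_kernels)
    outcome_tilt: float = 0.25
    covariate_missing_rates: dict = field(
        default_factory=lambda: dict(_DEFAULT_COVARIATE_MISSING_RATES))
    visit_missing_rates: dict = field(
        default_factory=lambda: dict(reference.REPORTED_VISIT_MISSINGNESS))
    windows: dict = field(default_factory=lambda: {k: tuple(v) for k, v in DEFAULT_WINDOWS.items()})

    def validate(self) -> "TruthParameters":
        if self.n < 10:
            raise TruthError(f"cohort size n={self.n} is degenerate (need >= 10)")
        probs = np.asarray(self.baseline_stage_probs, dtype=float)
        if probs.shape != (N_STAGES,) or abs(probs.sum() - 1.0) > 1e-9 or (probs < 0).any():
            raise TruthError("baseline_stage_probs must be a length-4 probability vector")
        for therapy in THERAPIES:
            if therapy not in self.kernels:
                raise TruthError(f"kernel missing for therapy {therapy!r}")
            for window in self.windows:
                k = np.asarray(self.kernels[therapy][window], dtype=float)
                if k.shape != (N_STAGES, N_STAGES):
                    raise TruthError(f"kernel[{therapy}][{window}] must be 4x4")
                if (k < 0).any():
                    raise TruthError(f"kernel[{therapy}][{window}] has negative entries")
                if np.abs(k.sum(axis=1) - 1.0).max() > 1e-12:
                    raise TruthError(
                        f"kernel[{therapy}][{window}] rows must sum to 1 within 1e-12")
        for var, rate in self.covariate_missing_rates.items():
            if not 0.0 <= rate <= 1.0:
                raise TruthError(f"covariate missing rate for {var!r} outside [0, 1]")
        for window, rate in self.visit_missing_rates.items():
            if not 0.0 <= rate <= 1.0:
                raise TruthError(f"visit missing rate for {window!r} outside [0, 1]")
        if self.target_shares is not None:
            shares = np.asarray([self.target_shares[t] for t in THERAPIES], dtype=float)
            if abs(shares.sum() - 1.0) > 1e-6 or (shares <= 0).any():
                raise TruthError("target_shares must be positive and sum to 1")
        return self

    def to_dict(self) -> dict:
        d = asdict(self)
        d["baseline_stage_probs"] = list(self.baseline_stage_probs)
        d["windows"] = {k: list(v) for k, v in self.windows.items()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "TruthParameters":
        d = _copy.deepcopy(d)
        d["baseline_stage_probs"] = tuple(d["baseline_stage_probs"])
        d["windows"] = {k: tuple(v) for k, v in d["windows"].items()}
        return cls(**d).validate()


def write_truth(truth: TruthParameters, path) -> Path:
    """Serialize ground truth to JSON (lossless round trip)."""
    truth.validate()
    path = Path(path)
    path.write_text(json.dumps(truth.to_dict(), indent=2, sort_keys=True) + "\n")
    return path


def read_truth(path) -> TruthParameters:
    return TruthParameters.from_dict(json.loads(Path(path).read_text()))


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    return (x - x.mean()) / (sd if sd > 0 else 1.0)


def _calibrate_intercepts(eta: np.ndarray, targets: np.ndarray,
                          tol: float = 1e-8, max_iter: int = 200) -> np.ndarray:
    """Find additive intercepts making mean softmax probabilities hit targets."""
    a = np.zeros(eta.shape[1])
    for _ in range(max_iter):
        z = eta + a
        z -= z.max(axis=1, keepdims=True)
        p = np.exp(z)
        p /= p.sum(axis=1, keepdims=True)
        mean = p.mean(axis=0)
        if np.abs(mean - targets).max() < tol:
            break
        a += np.log(targets / mean)
        a -= a.mean()
    return a


def _draw_categorical(rng: np.random.Generator, probs: np.ndarray) -> np.ndarray:
    """Row-wise categorical draw; probs is (n, k) row-stochastic."""
    cum = np.cumsum(probs, axis=1)
    u = rng.uniform(size=(probs.shape[0], 1))
    return (u > cum[:, :-1]).sum(axis=1)


def generate_cohort(params: TruthParameters,
                    ) -> tuple[CohortTable, TruthParameters]:
    """Generate a complete synthetic cohort (no missingness applied).

    Returns the cohort together with the (validated) ground truth that
    produced it.  Deterministic: identical parameters give an identical
    cohort, bit for bit.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    n = params.n

    # latent severity factor shared by the severity covariates
    z = rng.standard_normal(n)

    def mix(load, size=n):
        return load * z + np.sqrt(1.0 - load**2) * rng.standard_normal(size)

    age = np.exp(3.653 + 0.452 * rng.standard_normal(n)).clip(16, 95).round(1)
    bmi = (24.1 + 3.6 * rng.standard_normal(n)).clip(14, 50).round(1)
    duration = np.exp(1.79 + 1.10 * mix(0.20)).clip(0.1, 70).round(1)
    pasi = np.exp(2.197 + 1.155 * mix(0.40)).clip(0.1, 72).round(1)
    bsa = np.exp(2.639 + 1.00 * mix(0.35)).clip(0.1, 100).round(1)
    dlqi = np.rint((8.0 + 5.0 * mix(0.30)).clip(0, 30))

    cols = {"age": age, "bmi": bmi, "duration": duration,
            "pasi": pasi, "bsa": bsa, "dlqi": dlqi}
    for var in BINARY_COVARIATES:
        p0 = _BINARY_PROBS[var]
        load = _BINARY_SEVERITY_LOADING.get(var, 0.0)
        logit = np.log(p0 / (1 - p0)) + load * z
        p = 1.0 / (1.0 + np.exp(-logit))
        cols[var] = (rng.uniform(size=n) < p).astype(float)

    # baseline stage: ordinal probit on the latent severity factor
    thresholds = ndtri(np.cumsum(params.baseline_stage_probs)[:-1])
    v = mix(0.50)
    baseline_stage = np.searchsorted(thresholds, v)

    # treatment assignment: multinomial logit on severity covariates
    feats = {
        "pasi": _standardize(np.log(pasi + 0.5)),
        "dlqi": _standardize(dlqi),
        "duration": _standardize(np.log(duration + 0.5)),
        "stage": baseline_stage - baseline_stage.mean(),
    }
    eta = np.zeros((n, len(THERAPIES)))
    for j, therapy in enumerate(THERAPIES):
        coefs = params.assignment_coefs[therapy]
        eta[:, j] = coefs.get("intercept", 0.0) + sum(
            coefs.get(name, 0.0) * feats[name] for name in feats)
    if params.target_shares is not None:
        targets = np.asarray([params.target_shares[t] for t in THERAPIES])
        eta = eta + _calibrate_intercepts(eta, targets)
    eta -= eta.max(axis=1, keepdims=True)
    probs = np.exp(eta)
    probs /= probs.sum(axis=1, keepdims=True)
    therapy_idx = _draw_categorical(rng, probs)
    therapy = np.asarray(THERAPIES)[therapy_idx]

    patients = pd.DataFrame({"therapy": therapy, "baseline_stage": baseline_stage,
                             **cols})
    patients.index.name = "id"
    patients = patients[list(PATIENT_COLUMNS)]

    # follow-up visits: every visit's stage is an i.i.d. draw from the
    # patient's (optionally severity-tilted) kernel row; the last visit in a
    # window therefore realizes the window outcome.
    zsev = feats["pasi"]
    dest = np.arange(N_STAGES) - (N_STAGES - 1) / 2.0
    visit_frames = []
    for window, (lo, hi) in params.windows.items():
        kern = np.stack([np.asarray(params.kernels[t][window], dtype=float)
                         for t in THERAPIES])
        rows = kern[therapy_idx, baseline_stage]  # (n, 4)
        with np.errstate(divide="ignore"):
            logits = np.log(rows) + params.outcome_tilt * zsev[:, None] * dest[None, :]
        logits -= logits.max(axis=1, keepdims=True)
        p = np.exp(logits)
        p /= p.sum(axis=1, keepdims=True)

        counts = 1 + rng.poisson(0.35, size=n)
        pid = np.repeat(np.arange(n), counts)
        days = rng.integers(lo + 1, hi + 1, size=counts.sum())
        stages = _draw_categorical(rng, p[pid])
        frame = pd.DataFrame({"id": pid, "day": days, "stage": stages})
        frame = frame.drop_duplicates(["id", "day"])
        visit_frames.append(frame)

    visits = pd.concat(visit_frames, ignore_index=True)
    visits = visits.sort_values(["id", "day"], kind="mergesort").reset_index(drop=True)
    # map stage back to a raw IGA score (stage 0 covers IGA 0 and 1)
    iga = visits["stage"].map(lambda s: _STAGE_TO_SCORE[s]).to_numpy(dtype=float)
    zero_stage = visits["stage"].to_numpy() == 0
    iga[zero_stage] = rng.integers(0, 2, size=int(zero_stage.sum()))
    visits = visits.assign(iga=iga.astype(int))[["id", "day", "iga"]]

    cohort = CohortTable(patients, visits).validate()
    return cohort, params


def apply_missingness(cohort: CohortTable, params: TruthParameters) -> CohortTable:
    """Mask covariates and delete follow-up windows, missing at random.

    Masking probabilities depend only on the baseline stage (observed for
    everyone, never masked itself), scaled so the marginal rate matches the
    configured one.  Therapy and baseline stage are never masked.  Visit
    deletion removes a patient's entire visit record inside a window with
    the configured per-window probability.
    """
    params.validate()
    rng = np.random.default_rng([params.seed, 104729])
    out = cohort.copy()
    stage_c = out.patients["baseline_stage"].to_numpy() - \
        out.patients["baseline_stage"].to_numpy().mean()
    n = out.n

    def mar_probs(rate: float, slope: float) -> np.ndarray:
        # probabilities proportional to exp(slope * stage), rescaled by
        # bisection so the marginal mean equals the configured rate even
        # when individual probabilities saturate at 1
        if rate == 0.0:
            return np.zeros(n)
        if rate == 1.0:
            return np.ones(n)
        w = np.exp(slope * stage_c)
        lo, hi = 0.0, 1.0 / w.min()
        for _ in range(60):
            c = (lo + hi) / 2.0
            if np.clip(c * w, 0.0, 1.0).mean() < rate:
                lo = c
            else:
                hi = c
        return np.clip(c * w, 0.0, 1.0)

    for var in COVARIATES:
        rate = params.covariate_missing_rates.get(var, 0.0)
        mask = rng.uniform(size=n) < mar_probs(rate, 0.8)
        if mask.any():
            out.patients.loc[out.patients.index[mask], var] = np.nan

    drop_ids = []
    for window, (lo, hi) in params.windows.items():
        rate = params.visit_missing_rates.get(window, 0.0)
        gone = rng.uniform(size=n) < mar_probs(rate, 0.15)
        if gone.any():
            gone_ids = out.patients.index.to_numpy()[gone]
            in_window = out.visits["day"].between(lo + 1, hi)
            drop_ids.append(in_window & out.visits["id"].isin(gone_ids))
    if drop_ids:
        drop = np.logical_or.reduce([m.to_numpy() for m in drop_ids])
        out.visits = out.visits.loc[~drop].reset_index(drop=True)
    return out.validate()
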