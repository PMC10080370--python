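"""Multiple imputation of baseline covariates by chained equations.

Continuous covariates are imputed by predictive mean matching (PMM): a
Bayesian linear model on all other covariates (plus baseline stage and
therapy) is fit to the observed cases, coefficients are drawn from their
approximate posterior, and each missing case receives the observed value of
a randomly chosen donor among the ``k`` cases with the closest predicted
mean.  Imputed values are therefore always members of the observed support.
Binary covariates are imputed by logistic-regression probability draws.

Follow-up visit records are never touched: missing follow-up outcomes are
handled downstream by last-observation-carried-forward at estimation time,
not by multiple imputation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve
from sklearn.linear_model import LogisticRegression

from .cohort import (
    BINARY_COVARIATES,
    CONTINUOUS_COVARIATES,
    COVARIATES,
    CohortTable,
    THERAPIES,
)

logger = logging.getLogger(__name__)


@dataclass
class ImputedSet:
    """M completed copies of one cohort plus provenance."""

    m: int
    cohorts: list
    provenance: dict
    source_visits: pd.DataFrame

    def __post_init__(self):
        if self.m != len(self.cohorts):
            raise ValueError("m must equal the number of completed cohorts")


def _design(patients: pd.DataFrame, target: str) -> np.ndarray:
    """Design matrix for imputing ``target``: intercept + all other
    covariates + ordinal baseline stage + therapy indicators."""
    cols = [c for c in COVARIATES if c != target]
    X = patients[cols].to_numpy(dtype=float)
    stage = patients["baseline_stage"].to_numpy(dtype=float)[:, None]
    ther = np.column_stack([
        (patients["therapy"] == t).to_numpy(dtype=float) for t in THERAPIES[1:]
    ])
    return np.column_stack([np.ones(len(patients)), X, stage, ther])


def _pmm_impute(X: np.ndarray, y: np.ndarray, obs: np.ndarray,
                rng: np.random.Generator, k: int) -> np.ndarray:
    """PMM draw for the missing entries of y; returns imputed values."""
    Xo, yo = X[obs], y[obs]
    Xm = X[~obs]
    p = X.shape[1]
    xtx = Xo.T @ Xo
    ridge = 1e-8 * np.trace(xtx) / p
    xtx[np.diag_indices_from(xtx)] += ridge
    try:
        chol = cho_factor(xtx)
    except np.linalg.LinAlgError:
        logger.warning("singular design while imputing; sampling from observed marginal")
        return rng.choice(yo, size=len(Xm))
    beta_hat = cho_solve(chol, Xo.T @ yo)
    resid = yo - Xo @ beta_hat
    df = max(len(yo) - p, 1)
    sigma2 = resid @ resid / rng.chisquare(df)
    # posterior draw of the coefficients: N(beta_hat, sigma2 (XtX)^-1)
    L = np.linalg.cholesky(np.linalg.inv(xtx))
    beta_star = beta_hat + L @ rng.standard_normal(p) * np.sqrt(sigma2)
    pred_obs = Xo @ beta_hat
    pred_mis = Xm @ beta_star
    # k nearest observed predictions per missing case (vectorized)
    k_eff = min(k, len(yo))
    dist = np.abs(pred_obs[None, :] - pred_mis[:, None])
    nearest = np.argpartition(dist, k_eff - 1, axis=1)[:, :k_eff]
    pick = rng.integers(k_eff, size=len(Xm))
    return yo[nearest[np.arange(len(Xm)), pick]]


def _logistic_impute(X: np.ndarray, y: np.ndarray, obs: np.ndarray,
                     rng: np.random.Generator) -> np.ndarray:
    Xo, yo = X[obs], y[obs]
    Xm = X[~obs]
    classes = np.unique(yo)
    if len(classes) < 2:
        return np.full(len(Xm), classes[0])
    try:
        model = LogisticRegression(max_iter=500, solver="newton-cholesky")
        model.fit(Xo[:, 1:], yo)  # sklearn adds its own intercept
        p1 = model.predict_proba(Xm[:, 1:])[:, list(model.classes_).index(1.0)]
    except Exception:  # non-convergence or degenerate fit
        logger.warning("logistic imputation model failed; sampling from marginal")
        p1 = np.full(len(Xm), yo.mean())
    return (rng.uniform(size=len(Xm)) < p1).astype(float)


def impute(cohort: CohortTable, m: int = 20, cycles: int = 10,
           seed: int = 0, pmm_k: int = 5) -> ImputedSet:
    """Produce ``m`` completed copies of the cohort by chained equations.

    Parameters
    ----------
    m : number of imputations (>= 2).
    cycles : full variable-by-variable sweeps per copy.
    pmm_k : PMM donor-pool size for continuous covariates.
    """
    if m < 2:
        raise ValueError("multiple imputation needs m >= 2 (Rubin pooling is undefined for m=1)")
    cohort.validate()
    if cohort.patients["baseline_stage"].isna().any():
        raise ValueError("baseline_stage must be fully observed")
    masks = {v: cohort.patients[v].isna().to_numpy() for v in COVARIATES}
    for v, mask in masks.items():
        if mask.all():
            raise ValueError(f"covariate {v!r} is 100% missing; cannot impute")
    needs = [v for v in COVARIATES if masks[v].any()]
    # impute the least-missing variables first within each sweep
    needs.sort(key=lambda v: (int(masks[v].sum()), v))

    cohorts = []
    for i in range(m):
        rng = np.random.default_rng([seed, i])
        patients = cohort.patients.copy()
        # initial fill: random draws from the observed values
        for v in needs:
            obs_vals = cohort.patients.loc[~masks[v], v].to_numpy()
            patients.loc[masks[v], v] = rng.choice(obs_vals, size=int(masks[v].sum()))
        for _ in range(cycles if needs else 0):
            for v in needs:
                mask = masks[v]
                X = _design(patients, v)
                obs = ~mask
                y_full = patients[v].to_numpy(dtype=float)
                if v in CONTINUOUS_COVARIATES:
                    imp = _pmm_impute(X, y_full, obs, rng, pmm_k)
                else:
                    imp = _logistic_impute(X, y_full, obs, rng)
                patients.loc[mask, v] = imp
        cohorts.append(CohortTable(patients, cohort.visits.copy()))

    return ImputedSet(
        m=m, cohorts=cohorts,
        provenance={"seed": seed, "cycles": cycles, "m": m, "pmm_k": pmm_k},
        source_visits=cohort.visits.copy(),
    )


def locf_check(imputed: ImputedSet) -> dict:
    """Verify imputation left every visit table untouched.

    Follow-up outcomes are deliberately outside the imputation model; this
    check guards the module contract.
    """
    violations = [i for i, c in enumerate(imputed.cohorts)
                  if not c.visits.reset_index(drop=True).equals(
                      imputed.source_visits.reset_index(drop=True))]
    return {"ok": not violations, "n_checked": imputed.m, "violations": violations}
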