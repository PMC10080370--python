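"""Tri-directional 1:1 nearest-neighbor matching with replacement.

Every patient anchors one triple: itself plus its Mahalanobis-nearest
neighbor in each of the two other therapy arms.  Matching is *with
replacement* — a unit may be the nearest neighbor of many anchors — so a
unit's frequency weight is the number of triples it appears in.  The metric
covariance is estimated once on the pooled (all-arm) completed data; ties
are broken toward the lowest patient id, making the procedure deterministic
for a given input.

Run after imputation: the matching covariates must be fully observed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from scipy import stats

from .cohort import (
    BINARY_COVARIATES,
    CohortTable,
    MATCHING_COVARIATES,
    THERAPIES,
)

logger = logging.getLogger(__name__)

_SLOT = {t: f"{t}_id" for t in THERAPIES}


class MatchingError(ValueError):
    pass


@dataclass
class MatchedCohort:
    """One triple per anchor patient; slots named ``<therapy>_id``."""

    triples: pd.DataFrame  # columns anchor_id, traditional_id, systemic_id, biologic_id
    imputation_index: int = 0

    @property
    def n_triples(self) -> int:
        return len(self.triples)

    def weights(self, therapy: str) -> pd.Series:
        """Frequency weight per distinct unit of one therapy arm."""
        return self.triples[_SLOT[therapy]].value_counts().sort_index()

    def validate(self, cohort: CohortTable | None = None) -> "MatchedCohort":
        for t in THERAPIES:
            if self.triples[_SLOT[t]].isna().any():
                raise MatchingError(f"unfilled {t} slot in triples")
        if cohort is not None:
            if len(self.triples) != cohort.n:
                raise MatchingError("every patient must anchor exactly one triple")
            ther = cohort.patients["therapy"]
            for t in THERAPIES:
                if not ther.loc[self.triples[_SLOT[t]]].eq(t).all():
                    raise MatchingError(f"{t} slot holds a unit from another arm")
        return self


def mahalanobis_distance(x, y, s_inv) -> float:
    """sqrt((x - y)' S^-1 (x - y)); requires a symmetric PD ``s_inv``."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    s_inv = np.asarray(s_inv, dtype=float)
    if x.shape != y.shape or s_inv.shape != (x.size, x.size):
        raise ValueError("dimension mismatch between vectors and s_inv")
    if not np.allclose(s_inv, s_inv.T, rtol=1e-10, atol=1e-12):
        raise ValueError("s_inv must be symmetric")
    np.linalg.cholesky(s_inv)  # raises LinAlgError if not positive definite
    d = x - y
    return float(np.sqrt(max(d @ s_inv @ d, 0.0)))


def matching_matrix(cohort: CohortTable) -> np.ndarray:
    """Covariate matrix used for the metric, in MATCHING_COVARIATES order."""
    patients = cohort.patients
    if patients[list(MATCHING_COVARIATES[:-1])].isna().any().any():
        raise MatchingError("matching requires fully observed covariates (impute first)")
    return patients[list(MATCHING_COVARIATES)].to_numpy(dtype=float)


def pooled_covariance(X: np.ndarray) -> np.ndarray:
    """Covariance of the pooled cohort, ridge-regularized if singular."""
    S = np.cov(X, rowvar=False)
    try:
        np.linalg.cholesky(S)
    except np.linalg.LinAlgError:
        eps = 1e-6 * np.trace(S) / S.shape[0]
        logger.warning("singular pooled covariance; adding ridge %.3g", eps)
        S = S + eps * np.eye(S.shape[0])
        np.linalg.cholesky(S)
    return S


def _whiten(X: np.ndarray, S: np.ndarray) -> np.ndarray:
    # S^-1 = L L'  =>  d_M(x, y) = ||L'(x - y)||_2
    L = np.linalg.cholesky(np.linalg.inv(S))
    return X @ L


def _nearest(Zq: np.ndarray, Zp: np.ndarray, pool_ids: np.ndarray,
             chunk: int = 1024) -> np.ndarray:
    """Id of the nearest pool unit for each query row (ties -> lowest id)."""
    out = np.empty(len(Zq), dtype=pool_ids.dtype)
    for s in range(0, len(Zq), chunk):
        d = cdist(Zq[s:s + chunk], Zp, metric="sqeuclidean")
        out[s:s + chunk] = pool_ids[np.argmin(d, axis=1)]
    return out


def match_three_groups(cohort: CohortTable, s: np.ndarray | None = None,
                       imputation_index: int = 0) -> MatchedCohort:
    """Build one matched triple per patient.

    Parameters
    ----------
    s : optional pre-computed covariance matrix for the metric; by default
        the pooled covariance of the cohort's matching covariates.
    """
    counts = cohort.therapy_counts()
    for t in THERAPIES:
        if counts.get(t, 0) == 0:
            raise MatchingError(f"therapy arm {t!r} is empty; cannot match")
    X = matching_matrix(cohort)
    S = pooled_covariance(X) if s is None else np.asarray(s, dtype=float)
    Z = _whiten(X, S)
    ids = cohort.patients.index.to_numpy()
    therapy = cohort.patients["therapy"].to_numpy()

    # sort each arm's pool by id so argmin tie-breaks toward the lowest id
    pools = {}
    for t in THERAPIES:
        rows = np.flatnonzero(therapy == t)
        rows = rows[np.argsort(ids[rows], kind="stable")]
        pools[t] = (Z[rows], ids[rows])

    triples = pd.DataFrame({"anchor_id": ids})
    for t in THERAPIES:
        slot = np.empty(len(ids), dtype=ids.dtype)
        own = therapy == t
        slot[own] = ids[own]
        Zp, pool_ids = pools[t]
        if (~own).any():
            slot[~own] = _nearest(Z[~own], Zp, pool_ids)
        triples[_SLOT[t]] = slot
    return MatchedCohort(triples, imputation_index).validate(cohort)


def _weighted_stats(values: np.ndarray, weights: np.ndarray) -> tuple:
    mean = np.average(values, weights=weights)
    var = np.average((values - mean) ** 2, weights=weights)
    return mean, var


def balance_diagnostics(cohort: CohortTable, matched: MatchedCohort) -> pd.DataFrame:
    """Pre- vs post-matching balance for every matching covariate.

    For each covariate and each pairwise arm contrast, reports the absolute
    standardized mean difference (denominator: pre-matching pooled SD of the
    two arms) and a two-sample test p-value — Welch t-test for continuous
    covariates, chi-squared for binary — before and after matching (the
    post-matching test runs on the frequency-weight-expanded samples).
    """
    matched.validate(cohort)
    patients = cohort.patients
    rows = []
    pairs = [(a, b) for i, a in enumerate(THERAPIES) for b in THERAPIES[i + 1:]]
    for var in MATCHING_COVARIATES:
        vals = patients[var].astype(float) if var != "baseline_stage" \
            else patients["baseline_stage"].astype(float)
        for a, b in pairs:
            pre_a = vals[patients["therapy"] == a].dropna().to_numpy()
            pre_b = vals[patients["therapy"] == b].dropna().to_numpy()
            sd = np.sqrt((pre_a.var(ddof=1) + pre_b.var(ddof=1)) / 2)
            sd = sd if sd > 0 else 1.0
            smd_pre = abs(pre_a.mean() - pre_b.mean()) / sd

            wa = matched.weights(a)
            wb = matched.weights(b)
            post_a = vals.loc[wa.index].to_numpy()
            post_b = vals.loc[wb.index].to_numpy()
            mean_a, _ = _weighted_stats(post_a, wa.to_numpy())
            mean_b, _ = _weighted_stats(post_b, wb.to_numpy())
            smd_post = abs(mean_a - mean_b) / sd

            exp_a = np.repeat(post_a, wa.to_numpy())
            exp_b = np.repeat(post_b, wb.to_numpy())
            if var in BINARY_COVARIATES:
                p_pre = _chi2_p(pre_a, pre_b)
                p_post = _chi2_p(exp_a, exp_b)
            else:
                p_pre = stats.ttest_ind(pre_a, pre_b, equal_var=False).pvalue
                p_post = stats.ttest_ind(exp_a, exp_b, equal_var=False).pvalue
            rows.append({"covariate": var, "contrast": f"{a}_vs_{b}",
                         "smd_pre": smd_pre, "smd_post": smd_post,
                         "p_pre": float(p_pre), "p_post": float(p_post)})
    return pd.DataFrame(rows)


def _chi2_p(a: np.ndarray, b: np.ndarray) -> float:
    table = np.array([[np.sum(a == 1), np.sum(a == 0)],
                      [np.sum(b == 1), np.sum(b == 0)]])
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        return 1.0
    return float(stats.chi2_contingency(table, correction=False).pvalue)
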