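"""Mahalanobis matching: metric properties, oracle equivalence, balance."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from psortransit.cohort import THERAPIES
from psortransit.match import (
    MatchingError,
    balance_diagnostics,
    mahalanobis_distance,
    match_three_groups,
    matching_matrix,
    pooled_covariance,
)

from conftest import make_cohort, random_mini_cohort


class TestMahalanobisDistance:
    def test_self_distance_zero(self):
        x = np.array([1.0, -2.0, 3.5])
        assert mahalanobis_distance(x, x, np.eye(3)) == 0.0

    def test_identity_metric_is_euclidean(self):
        assert mahalanobis_distance([3.0, 4.0], [0.0, 0.0], np.eye(2)) == \
            pytest.approx(5.0)

    def test_diagonal_metric_quadratic_form(self):
        # (2,1) under diag(1/4, 1): sqrt(4/4 + 1) = sqrt(2)
        s_inv = np.diag([0.25, 1.0])
        assert mahalanobis_distance([2.0, 1.0], [0.0, 0.0], s_inv) == \
            pytest.approx(np.sqrt(2.0))

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError, match="dimension"):
            mahalanobis_distance([1.0, 2.0], [1.0], np.eye(2))

    def test_non_positive_definite_rejected(self):
        with pytest.raises(np.linalg.LinAlgError):
            mahalanobis_distance([1.0, 0.0], [0.0, 0.0],
                                 np.array([[1.0, 2.0], [2.0, 1.0]]))

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(-50, 50), min_size=3, max_size=3),
           st.lists(st.floats(-50, 50), min_size=3, max_size=3))
    def test_symmetry_and_nonnegativity(self, x, y):
        s_inv = np.diag([1.0, 0.5, 2.0])
        d_xy = mahalanobis_distance(x, y, s_inv)
        assert d_xy >= 0.0
        assert d_xy == pytest.approx(mahalanobis_distance(y, x, s_inv))


def diag_metric(cohort) -> np.ndarray:
    """Well-conditioned diagonal metric from marginal variances."""
    X = matching_matrix(cohort)
    return np.diag(np.clip(X.var(axis=0), 1e-2, None))


def brute_force_triples(cohort, s):
    """Exhaustive nearest-neighbor search, lowest-id tie break."""
    s_inv = np.linalg.inv(s)
    s_inv = (s_inv + s_inv.T) / 2.0
    X = matching_matrix(cohort)
    ids = cohort.patients.index.to_numpy()
    therapy = cohort.patients["therapy"].to_numpy()
    rows = {pid: X[i] for i, pid in enumerate(ids)}
    triples = {}
    for anchor, t_a in zip(ids, therapy):
        slots = {}
        for t in THERAPIES:
            if t == t_a:
                slots[t] = anchor
                continue
            best, best_d = None, np.inf
            for cand in sorted(ids[therapy == t]):
                d = mahalanobis_distance(rows[anchor], rows[cand], s_inv)
                if d < best_d - 1e-12:
                    best, best_d = cand, d
            slots[t] = best
        triples[anchor] = slots
    return triples


class TestMatchThreeGroups:
    def test_three_patient_forced_matching(self, tri_cohort):
        matched = match_three_groups(tri_cohort, s=np.eye(17))
        assert matched.n_triples == 3
        for t in THERAPIES:
            w = matched.weights(t)
            assert list(w.values) == [3]
        # every triple contains exactly the same three patients
        for _, row in matched.triples.iterrows():
            assert {row["traditional_id"], row["systemic_id"],
                    row["biologic_id"]} == {1, 2, 3}

    def test_matches_brute_force_oracle(self):
        """Chunked whitened-space search equals exhaustive search.  A fixed
        well-conditioned diagonal metric keeps nearest neighbors well
        defined at n < p, where an estimated covariance would be singular
        and every pairwise distance nearly identical."""
        rng = np.random.default_rng(424)
        for _ in range(20):
            cohort = random_mini_cohort(rng)
            S = diag_metric(cohort)
            fast = match_three_groups(cohort, s=S)
            oracle = brute_force_triples(cohort, S)
            for _, row in fast.triples.iterrows():
                want = oracle[row["anchor_id"]]
                for t in THERAPIES:
                    assert row[f"{t}_id"] == want[t]

    def test_empty_arm_rejected(self):
        cohort = make_cohort([
            {"id": 0, "therapy": "traditional"},
            {"id": 1, "therapy": "biologic"},
        ])
        with pytest.raises(MatchingError, match="empty"):
            match_three_groups(cohort)

    def test_missing_covariates_rejected(self, default_params, small_cohort):
        from psortransit.simulate import apply_missingness
        masked = apply_missingness(small_cohort, default_params)
        with pytest.raises(MatchingError, match="impute"):
            match_three_groups(masked)

    def test_weights_sum_to_triple_count(self, small_cohort):
        matched = match_three_groups(small_cohort)
        assert matched.n_triples == small_cohort.n
        for t in THERAPIES:
            assert matched.weights(t).sum() == matched.n_triples

    def test_replacement_locality(self, small_cohort):
        """Under a fixed metric, dropping an unreferenced patient leaves
        all other triples unchanged."""
        S = pooled_covariance(matching_matrix(small_cohort))
        matched = match_three_groups(small_cohort, s=S)
        referenced = set()
        for t in THERAPIES:
            referenced |= set(matched.weights(t).index)
        unreferenced = [i for i in small_cohort.patients.index
                        if i not in referenced]
        # anchors are always referenced; weights only count slot appearances
        victim = unreferenced[0] if unreferenced else None
        assert victim is None  # every patient anchors its own triple
        # instead drop a patient and check only its own triples vanish/change
        drop = small_cohort.patients.index[5]
        reduced = small_cohort.copy()
        reduced.patients = reduced.patients.drop(drop)
        reduced.visits = reduced.visits[reduced.visits["id"] != drop]
        rematched = match_three_groups(reduced, s=S)
        before = matched.triples.set_index("anchor_id")
        after = rematched.triples.set_index("anchor_id")
        slot_cols = [f"{t}_id" for t in THERAPIES]
        untouched = [a for a in after.index
                     if drop not in set(before.loc[a, slot_cols])]
        assert before.loc[untouched, slot_cols].equals(
            after.loc[untouched, slot_cols])


class TestBalanceDiagnostics:
    @pytest.mark.filterwarnings("ignore:Precision loss")
    def test_identical_groups_zero_smd(self):
        rows = []
        for i in range(9):
            rows.append({"id": i, "therapy": THERAPIES[i % 3],
                         "pasi": float(10 + i // 3),
                         "baseline_stage": i // 3})
        cohort = make_cohort(rows)
        matched = match_three_groups(cohort, s=np.eye(17))
        report = balance_diagnostics(cohort, matched)
        sub = report[report.covariate.isin(["pasi", "baseline_stage"])]
        assert (sub["smd_pre"] < 1e-12).all()
        assert (sub["smd_post"] < 1e-12).all()

    def test_matching_reduces_confounded_imbalance(self, small_cohort):
        """The generator's severity confounding: matching must shrink the
        pasi imbalance between biologic and traditional arms, and shrink
        every clearly imbalanced contrast."""
        matched = match_three_groups(small_cohort)
        report = balance_diagnostics(small_cohort, matched)
        pasi = report[(report.covariate == "pasi") &
                      (report.contrast == "traditional_vs_biologic")].iloc[0]
        assert pasi["smd_post"] < pasi["smd_pre"]
        confounded = report[report.smd_pre > 0.15]
        assert not confounded.empty
        assert (confounded["smd_post"] < confounded["smd_pre"]).all()
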