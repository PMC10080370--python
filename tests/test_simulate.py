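"""Generator: calibration, determinism, missingness mechanics, ground truth IO."""

import json

import numpy as np
import pandas as pd
import pytest

from psortransit import io as cio
from psortransit.cohort import COVARIATES, THERAPIES
from psortransit.simulate import (
    TruthError,
    TruthParameters,
    apply_missingness,
    generate_cohort,
    read_truth,
    write_truth,
)
from psortransit.transitions import bin_iga


def identity_kernels():
    eye = np.eye(4).tolist()
    return {t: {"w1": eye, "w2": eye} for t in THERAPIES}


class TestGenerateCohort:
    def test_arm_shares_hit_reported_targets(self):
        """Assignment intercept calibration reproduces the published arm
        shares (biologic 32.6%, traditional 53.7%, systemic 13.7%)."""
        cohort, truth = generate_cohort(TruthParameters(n=10000, seed=5))
        shares = cohort.therapy_counts() / cohort.n
        for therapy, target in truth.target_shares.items():
            assert shares[therapy] == pytest.approx(target, abs=0.02)

    def test_identity_kernel_freezes_stage(self):
        """With identity kernels every visit's binned IGA equals baseline."""
        params = TruthParameters(n=300, seed=2, kernels=identity_kernels(),
                                 outcome_tilt=0.0)
        cohort, _ = generate_cohort(params)
        stages = cohort.visits["iga"].map(bin_iga)
        baseline = cohort.patients.loc[cohort.visits["id"], "baseline_stage"]
        assert (stages.to_numpy() == baseline.to_numpy()).all()

    def test_determinism_byte_identical_csv(self, tmp_path):
        params = TruthParameters(n=200, seed=9)
        for run in ("a", "b"):
            cohort, _ = generate_cohort(params)
            cio.write_cohort(cohort, tmp_path / run)
        for name in (cio.PATIENTS_FILE, cio.VISITS_FILE):
            assert (tmp_path / "a" / name).read_bytes() == \
                (tmp_path / "b" / name).read_bytes()

    def test_kernel_convergence_without_confounding(self):
        """Empirical per-therapy matrices converge to the kernels when
        assignment is random and the severity tilt is off."""
        coefs = {t: {"intercept": 0.0} for t in THERAPIES}
        params = TruthParameters(
            n=20000, seed=31, outcome_tilt=0.0, assignment_coefs=coefs,
            target_shares={t: 1 / 3 for t in THERAPIES},
            visit_missing_rates={"w1": 0.0, "w2": 0.0})
        cohort, truth = generate_cohort(params)
        from psortransit.transitions import estimate_transitions
        for therapy in THERAPIES:
            for window in ("w1", "w2"):
                est = estimate_transitions(cohort, None, therapy, window)
                kernel = np.asarray(truth.kernels[therapy][window])
                # 0.02 absolute, widened to 4 binomial SEs for sparse rows
                tol = np.maximum(
                    0.02, 4.0 * np.sqrt(kernel * (1 - kernel) /
                                        est.n_row[:, None]))
                assert (np.abs(est.p - kernel) < tol).all()

    def test_bad_kernel_rejected(self):
        kernels = identity_kernels()
        kernels["biologic"]["w1"] = (np.eye(4) * 0.99).tolist()
        with pytest.raises(TruthError, match="sum to 1"):
            generate_cohort(TruthParameters(n=100, kernels=kernels))

    def test_degenerate_n_rejected(self):
        with pytest.raises(TruthError, match="degenerate"):
            generate_cohort(TruthParameters(n=5))


class TestApplyMissingness:
    def test_zero_rates_identity(self):
        params = TruthParameters(
            n=200, seed=4,
            covariate_missing_rates={v: 0.0 for v in COVARIATES},
            visit_missing_rates={"w1": 0.0, "w2": 0.0})
        cohort, _ = generate_cohort(params)
        masked = apply_missingness(cohort, params)
        pd.testing.assert_frame_equal(masked.patients, cohort.patients)
        pd.testing.assert_frame_equal(masked.visits, cohort.visits)

    def test_covariate_rates_in_reported_range(self):
        """Achieved marginal missingness stays near the 1.5%-8.1% band."""
        params = TruthParameters(n=10000, seed=6)
        cohort, _ = generate_cohort(params)
        masked = apply_missingness(cohort, params)
        for var, rate in params.covariate_missing_rates.items():
            frac = masked.patients[var].isna().mean()
            assert 0.005 <= frac <= 0.095
            assert frac == pytest.approx(rate, abs=0.01)

    def test_visit_window_rates(self):
        """Fraction of patients with no visit in a window matches the
        published 62.1% / 48.8%."""
        params = TruthParameters(n=10000, seed=6)
        cohort, _ = generate_cohort(params)
        masked = apply_missingness(cohort, params)
        for window, (lo, hi) in params.windows.items():
            seen = masked.visits.loc[
                masked.visits["day"].between(lo + 1, hi), "id"].unique()
            frac = 1.0 - len(seen) / cohort.n
            assert frac == pytest.approx(
                params.visit_missing_rates[window], abs=0.02)

    def test_baseline_and_therapy_never_masked(self):
        params = TruthParameters(n=2000, seed=8)
        cohort, _ = generate_cohort(params)
        masked = apply_missingness(cohort, params)
        assert not masked.patients["baseline_stage"].isna().any()
        assert not masked.patients["therapy"].isna().any()

    def test_bad_rate_rejected(self):
        params = TruthParameters(n=100, visit_missing_rates={"w1": 1.2, "w2": 0.0})
        cohort, _ = generate_cohort(TruthParameters(n=100))
        with pytest.raises(TruthError, match="outside"):
            apply_missingness(cohort, params)


class TestTruthIO:
    def test_round_trip(self, tmp_path):
        truth = TruthParameters(n=500, seed=42)
        path = write_truth(truth, tmp_path / "truth.json")
        assert read_truth(path) == truth

    def test_invalid_kernel_refused(self, tmp_path):
        kernels = identity_kernels()
        kernels["systemic"]["w2"][0][0] = 0.99
        with pytest.raises(TruthError):
            write_truth(TruthParameters(n=100, kernels=kernels),
                        tmp_path / "t.json")

    def test_seed_is_only_field_differing(self, tmp_path):
        a = json.loads(write_truth(TruthParameters(n=100, seed=42),
                                   tmp_path / "a.json").read_text())
        b = json.loads(write_truth(TruthParameters(n=100, seed=43),
                                   tmp_path / "b.json").read_text())
        diff = {k for k in a if a[k] != b[k]}
        assert diff == {"seed"}
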