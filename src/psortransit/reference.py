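"""Published point estimates from the multicenter Chinese psoriasis registry
cohort (8767 plaque-psoriasis patients, three therapy arms) whose analysis
this package reimplements.

These numbers are *inputs*: they serve as worked-example fixtures for the
contrast arithmetic, as realistic defaults for the synthetic-cohort
generator's transition kernels, and as calibration targets (arm shares,
missingness rates).  All probabilities are printed to 2 decimals; a few rows
therefore sum to 0.99 or 1.01.
"""

from __future__ import annotations

import numpy as np

from .cohort import STAGE_LABELS

#: Pooled transition probability point estimates, baseline stage (rows,
#: IGA 0/1, 2, 3, 4) to follow-up stage (columns), per population and
#: follow-up window ("w1" = 0-1 month, "w2" = 1-12 months).
TRANSITION_POINT_ESTIMATES = {
    "overall": {
        "w1": [[0.80, 0.12, 0.06, 0.02],
               [0.18, 0.74, 0.06, 0.01],
               [0.18, 0.13, 0.68, 0.02],
               [0.19, 0.14, 0.07, 0.60]],
        "w2": [[0.54, 0.26, 0.16, 0.05],
               [0.34, 0.48, 0.14, 0.04],
               [0.35, 0.24, 0.37, 0.04],
               [0.36, 0.29, 0.14, 0.22]],
    },
    "traditional": {
        "w1": [[0.83, 0.10, 0.05, 0.02],
               [0.15, 0.78, 0.05, 0.01],
               [0.15, 0.10, 0.74, 0.02],
               [0.17, 0.12, 0.03, 0.67]],
        "w2": [[0.61, 0.19, 0.15, 0.05],
               [0.31, 0.54, 0.12, 0.04],
               [0.30, 0.20, 0.47, 0.03],
               [0.33, 0.23, 0.12, 0.31]],
    },
    "systemic": {
        "w1": [[0.85, 0.05, 0.07, 0.04],
               [0.25, 0.70, 0.04, 0.01],
               [0.17, 0.12, 0.70, 0.02],
               [0.16, 0.10, 0.06, 0.68]],
        "w2": [[0.61, 0.18, 0.16, 0.05],
               [0.38, 0.47, 0.12, 0.03],
               [0.33, 0.24, 0.40, 0.03],
               [0.30, 0.27, 0.14, 0.29]],
    },
    "biologic": {
        "w1": [[0.73, 0.20, 0.08, 0.00],
               [0.15, 0.73, 0.10, 0.02],
               [0.23, 0.16, 0.59, 0.03],
               [0.23, 0.18, 0.10, 0.49]],
        "w2": [[0.41, 0.39, 0.16, 0.04],
               [0.34, 0.43, 0.18, 0.05],
               [0.42, 0.29, 0.25, 0.04],
               [0.41, 0.34, 0.14, 0.10]],
    },
}

#: Published between-therapy differences in transition probability
#: (elementwise, first arm minus second arm).
CONTRAST_POINT_ESTIMATES = {
    ("biologic", "traditional"): {
        "w1": [[-0.10, 0.10, 0.02, -0.02],
               [0.00, -0.05, 0.04, 0.01],
               [0.08, 0.06, -0.15, 0.01],
               [0.06, 0.06, 0.06, -0.18]],
        "w2": [[-0.20, 0.20, 0.01, -0.01],
               [0.03, -0.11, 0.07, 0.02],
               [0.12, 0.09, -0.22, 0.01],
               [0.08, 0.11, 0.02, -0.21]],
    },
    ("biologic", "systemic"): {
        "w1": [[-0.12, 0.15, 0.01, -0.04],
               [-0.10, 0.03, 0.05, 0.01],
               [0.06, 0.04, -0.11, 0.01],
               [0.06, 0.08, 0.04, -0.19]],
        "w2": [[-0.20, 0.21, 0.00, -0.01],
               [-0.05, -0.04, 0.06, 0.03],
               [0.09, 0.04, -0.15, 0.01],
               [0.11, 0.08, 0.01, -0.19]],
    },
}

#: Reported cohort composition: arm shares of the 8767 analysed patients.
REPORTED_ARM_SHARES = {"traditional": 0.537, "systemic": 0.137, "biologic": 0.326}

#: Reported fraction of patients with no follow-up IGA in each window.
REPORTED_VISIT_MISSINGNESS = {"w1": 0.621, "w2": 0.488}

#: Reported range of per-covariate missingness.
REPORTED_COVARIATE_MISSING_RANGE = (0.015, 0.081)

REPORTED_N = 8767


def transition_matrix(population: str, window: str) -> np.ndarray:
    """Published 4x4 point-estimate matrix as a float array."""
    return np.asarray(TRANSITION_POINT_ESTIMATES[population][window], dtype=float)


def contrast_matrix(arm_a: str, arm_b: str, window: str) -> np.ndarray:
    """Published 4x4 difference matrix (arm_a minus arm_b)."""
    return np.asarray(CONTRAST_POINT_ESTIMATES[(arm_a, arm_b)][window], dtype=float)


def stage_index(label: str) -> int:
    return STAGE_LABELS.index(label)
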