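"""Rubin-rule pooling of transition estimates across imputations.

With per-imputation point estimates q_1..q_M and within-imputation variances
u_1..u_M, the pooled estimate is the mean q̄, the within-variance W is the
mean of the u_m, the between-variance B is the sample variance of the q_m,
and the total variance is W + (1 + 1/M) B.  95% intervals default to the
normal quantile (q̄ ± 1.96 sqrt(total)); Rubin's t reference with
Barnard-Rubin-style degrees of freedom is available by option.  Pooling is
done on the probability scale, which keeps structurally empty cells at an
exact zero with a zero-width interval.

Between-therapy contrasts are pooled the same way on the per-imputation
elementwise differences, so the contrast point estimate equals the
difference of the pooled points exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .transitions import TransitionEstimate

Z95 = 1.959963984540054  # normal 97.5% quantile


@dataclass
class PooledResult:
    therapy: str
    window: str
    p: np.ndarray          # pooled 4x4 point estimates
    within: np.ndarray
    between: np.ndarray
    total_var: np.ndarray
    ci_lo: np.ndarray
    ci_hi: np.ndarray
    m: int


@dataclass
class ContrastResult:
    therapy_a: str
    therapy_b: str
    window: str
    d: np.ndarray          # pooled 4x4 differences (a - b)
    total_var: np.ndarray
    ci_lo: np.ndarray
    ci_hi: np.ndarray
    m: int


def _rubin(points: np.ndarray, withins: np.ndarray, ci_reference: str):
    """points, withins: (m, 4, 4) stacks -> (mean, W, B, total, halfwidth)."""
    m = points.shape[0]
    mean = points.mean(axis=0)
    W = withins.mean(axis=0)
    B = points.var(axis=0, ddof=1)
    total = W + (1.0 + 1.0 / m) * B
    if ci_reference == "normal":
        q = Z95
    elif ci_reference == "t":
        # Rubin's large-sample df; infinite (normal) where B vanishes
        with np.errstate(divide="ignore", invalid="ignore"):
            r = (1.0 + 1.0 / m) * B / W
            df = (m - 1) * (1.0 + 1.0 / r) ** 2
        df = np.where(np.isfinite(df), df, np.inf)
        q = np.where(np.isinf(df), Z95, stats.t.ppf(0.975, np.clip(df, 1.0, None)))
    else:
        raise ValueError(f"ci_reference must be 'normal' or 't', got {ci_reference!r}")
    half = q * np.sqrt(total)
    return mean, W, B, total, half


def _check_stack(estimates: list, what: str):
    if len(estimates) < 2:
        raise ValueError(f"Rubin pooling needs m >= 2 {what} (between-imputation "
                         "variance is undefined for m = 1)")
    first = estimates[0]
    for e in estimates[1:]:
        if e.therapy != first.therapy or e.window != first.window:
            raise ValueError("all estimates must share therapy and window")


def pool_rubin(estimates: list, ci_reference: str = "normal") -> PooledResult:
    """Pool per-imputation transition estimates with Rubin's rules."""
    _check_stack(estimates, "estimates")
    points = np.stack([e.p for e in estimates])
    withins = np.stack([e.var for e in estimates])
    mean, W, B, total, half = _rubin(points, withins, ci_reference)
    ci_lo = np.clip(mean - half, 0.0, 1.0)
    ci_hi = np.clip(mean + half, 0.0, 1.0)
    return PooledResult(estimates[0].therapy, estimates[0].window,
                        mean, W, B, total, ci_lo, ci_hi, len(estimates))


def difference_matrix(p_a: np.ndarray, p_b: np.ndarray) -> np.ndarray:
    """Elementwise difference of two transition matrices (a - b)."""
    p_a = np.asarray(p_a, dtype=float)
    p_b = np.asarray(p_b, dtype=float)
    if p_a.shape != p_b.shape:
        raise ValueError("matrices must share shape")
    return p_a - p_b


def contrast(estimates_a: list, estimates_b: list,
             ci_reference: str = "normal") -> ContrastResult:
    """Pool the per-imputation differences between two therapies.

    Contrasting a therapy's estimates with themselves yields the zero
    matrix with zero-width intervals.
    """
    _check_stack(estimates_a, "per therapy")
    _check_stack(estimates_b, "per therapy")
    if estimates_a[0].window != estimates_b[0].window:
        raise ValueError("contrast requires a common window")
    if len(estimates_a) != len(estimates_b):
        raise ValueError("contrast requires the same number of imputations per arm")
    m = len(estimates_a)
    window = estimates_a[0].window
    a_name, b_name = estimates_a[0].therapy, estimates_b[0].therapy
    if a_name == b_name and all(
            np.array_equal(ea.p, eb.p, equal_nan=True)
            for ea, eb in zip(estimates_a, estimates_b)):
        zero = np.zeros((4, 4))
        return ContrastResult(a_name, b_name, window, zero, zero.copy(),
                              zero.copy(), zero.copy(), m)
    points = np.stack([difference_matrix(ea.p, eb.p)
                       for ea, eb in zip(estimates_a, estimates_b)])
    withins = np.stack([ea.var + eb.var
                        for ea, eb in zip(estimates_a, estimates_b)])
    mean, W, B, total, half = _rubin(points, withins, ci_reference)
    ci_lo = np.clip(mean - half, -1.0, 1.0)
    ci_hi = np.clip(mean + half, -1.0, 1.0)
    return ContrastResult(a_name, b_name, window, mean, total, ci_lo, ci_hi, m)
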