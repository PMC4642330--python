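"""Correlation and paired-comparison statistics.

Pearson product-moment correlation with a two-sided t-test on n-2 degrees
of freedom is used throughout, including when one variable is binary
(point-biserial) or both are (phi coefficient) — this is what generic
correlation software computes on 0/1 vectors. A closed-form point-biserial
expression is provided separately as an algebraic cross-check.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class CorrelationResult:
    """Pearson correlation between a named pair of variables."""

    variable_pair: tuple[str, str]
    r: float
    n: int
    p_value: float

    @property
    def r_squared(self) -> float:
        return self.r ** 2


@dataclass(frozen=True)
class PairedComparison:
    """Paired two-sided Student's t-test over per-genome coefficient pairs."""

    t: float
    p_value: float
    m: int
    mean_difference: float


def _as_vector(v, name: str) -> np.ndarray:
    arr = np.asarray(v, dtype=float)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional")
    if np.isnan(arr).any():
        raise ValueError(f"{name} contains missing values")
    return arr


def pearson_with_p(x, y, names: tuple[str, str] = ("x", "y")) -> CorrelationResult:
    """Pearson r with its two-sided significance.

    p = 2 P(T_{n-2} >= |r| sqrt((n-2)/(1-r^2))). Raises on length mismatch,
    n < 3, or a constant input vector (undefined correlation).
    """
    xa = _as_vector(x, names[0])
    ya = _as_vector(y, names[1])
    if len(xa) != len(ya):
        raise ValueError(f"length mismatch: {len(xa)} vs {len(ya)}")
    n = len(xa)
    if n < 3:
        raise ValueError(f"need at least 3 observations, got {n}")
    for arr, name in ((xa, names[0]), (ya, names[1])):
        if np.ptp(arr) == 0:
            raise ValueError(f"undefined correlation: {name} is constant")
    if np.array_equal(xa, ya):
        # r(x, x) is identically 1; skip the numerical round-trip, which
        # can land one ulp below 1
        return CorrelationResult(names, 1.0, n, 0.0)
    r, p = stats.pearsonr(xa, ya)
    return CorrelationResult(names, float(r), n, float(p))


def point_biserial_closed_form(n0: int, n1: int, mean0: float, mean1: float,
                               sd_all: float) -> float:
    """Point-biserial correlation from group summaries.

    r = (mean1 - mean0)/sd_all * sqrt(p q) with p = n1/(n0+n1), q = 1 - p.
    ``sd_all`` is the population (divide-by-n) standard deviation of the
    pooled continuous variable — with the matching p q form this equals the
    Pearson r of the raw data algebraically, so the function serves as an
    independent oracle for ``pearson_with_p`` on binary y.
    """
    if n0 < 1 or n1 < 1:
        raise ValueError("both groups need at least one observation")
    if sd_all <= 0:
        raise ValueError("sd_all must be positive")
    n = n0 + n1
    p = n1 / n
    return (mean1 - mean0) / sd_all * math.sqrt(p * (1.0 - p))


def paired_ttest(a, b) -> PairedComparison:
    """Two-sided paired Student's t-test on aligned coefficient vectors.

    t = mean(d) / (sd(d)/sqrt(m)) on d = a - b with m - 1 degrees of
    freedom. A zero-variance difference vector (including a == b) is an
    error rather than an infinite or undefined t.
    """
    aa = _as_vector(a, "a")
    bb = _as_vector(b, "b")
    if len(aa) != len(bb):
        raise ValueError(f"length mismatch: {len(aa)} vs {len(bb)}")
    m = len(aa)
    if m < 2:
        raise ValueError(f"need at least 2 pairs, got {m}")
    d = aa - bb
    if np.ptp(d) == 0:
        raise ValueError("zero-variance differences: paired t is undefined")
    t, p = stats.ttest_rel(aa, bb)
    return PairedComparison(float(t), float(p), m, float(d.mean()))


def align_sign(fitness_r) -> np.ndarray:
    """Negate fitness-vs-strand coefficients so they are comparable to
    binary-essentiality coefficients (low fitness = essential, hence the
    native fitness correlation with leading-strand membership is negative).
    """
    return -np.asarray(fitness_r, dtype=float)
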