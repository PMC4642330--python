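"""Worked example: binarizing a continuous variable lowers its correlation.

Take x = 1, 2, ..., n. Against itself, r(x, x) = 1. Replace the second copy
by the indicator y = I(x >= c0) for a threshold c0 and the correlation
drops — the information lost to the binary encoding caps r strictly below
1, with the maximum attained when c0 sits at the median. The >=
(threshold-inclusive) convention was fixed by evaluating both >= and >
against the known sweep values; only >= reproduces the asymmetric tails.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from strandbias.correlation_stats import pearson_with_p


@dataclass(frozen=True)
class ThresholdSweep:
    """Per-threshold correlation between x = 1..n and I(x >= c0)."""

    n: int
    thresholds: tuple[int, ...]
    r: tuple[float, ...]
    p: tuple[float, ...]

    def as_rows(self):
        return list(zip(self.thresholds, self.r, self.p))


def binarize(x, c0: float) -> np.ndarray:
    """y_i = 1 if x_i >= c0 else 0; errors when the output would be constant
    (c0 at or below the minimum, or above the maximum, of x)."""
    arr = np.asarray(x, dtype=float)
    if arr.size == 0:
        raise ValueError("empty input")
    lo, hi = arr.min(), arr.max()
    if not (lo < c0 <= hi):
        raise ValueError(
            f"threshold {c0} outside ({lo}, {hi}]: binarized output would "
            "be constant"
        )
    return (arr >= c0).astype(int)


def threshold_correlation(n: int, c0: float) -> float:
    """Pearson r between x = 1..n and its own binarization at c0."""
    if n < 3:
        raise ValueError(f"need n >= 3, got {n}")
    x = np.arange(1, n + 1)
    y = binarize(x, c0)
    return pearson_with_p(x, y, names=("x", "binarized")).r


def identity_baseline(n: int) -> float:
    """r(x, x) for x = 1..n; equals 1 exactly."""
    if n < 3:
        raise ValueError(f"need n >= 3, got {n}")
    x = np.arange(1, n + 1)
    return pearson_with_p(x, x, names=("x", "x")).r


def sweep(n: int, thresholds) -> ThresholdSweep:
    """Apply threshold_correlation at each threshold, keeping p-values."""
    if n < 3:
        raise ValueError(f"need n >= 3, got {n}")
    x = np.arange(1, n + 1)
    rs, ps = [], []
    for c0 in thresholds:
        res = pearson_with_p(x, binarize(x, c0), names=("x", "binarized"))
        rs.append(res.r)
        ps.append(res.p_value)
    return ThresholdSweep(
        n=n,
        thresholds=tuple(int(c) for c in thresholds),
        r=tuple(rs),
        p=tuple(ps),
    )
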