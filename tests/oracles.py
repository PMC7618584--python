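"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written from first principles (explicit loops and sums)
and deliberately shares no code with the package.
"""

from __future__ import annotations

import math

import numpy as np


def icc2_oracle(a, b) -> float:
    """ICC(2,1) by explicit two-way ANOVA summation (subjects x methods)."""
    a = list(map(float, a))
    b = list(map(float, b))
    n = len(a)
    k = 2
    table = [[a[i], b[i]] for i in range(n)]
    grand = sum(sum(row) for row in table) / (n * k)
    row_means = [sum(row) / k for row in table]
    col_means = [sum(table[i][j] for i in range(n)) / n for j in range(k)]
    ss_rows = k * sum((m - grand) ** 2 for m in row_means)
    ss_cols = n * sum((m - grand) ** 2 for m in col_means)
    ss_tot = sum((table[i][j] - grand) ** 2 for i in range(n) for j in range(k))
    ss_err = ss_tot - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)


def mad_oracle(a, b) -> tuple[float, float]:
    """Mean absolute difference and its sample SD, elementwise."""
    d = [abs(float(x) - float(y)) for x, y in zip(a, b)]
    n = len(d)
    m = sum(d) / n
    var = sum((x - m) ** 2 for x in d) / (n - 1)
    return m, math.sqrt(var)


def bland_altman_oracle(a, b) -> tuple[float, float, float]:
    """Bias, sample SD of signed differences (a-b), 1.96*SD half-width."""
    d = [float(x) - float(y) for x, y in zip(a, b)]
    n = len(d)
    bias = sum(d) / n
    sd = math.sqrt(sum((x - bias) ** 2 for x in d) / (n - 1))
    return bias, sd, 1.96 * sd


def rotate_points_oracle(points: np.ndarray, centre, deg: float) -> np.ndarray:
    """Explicit 2D rotation of points about a centre (image coords, y down)."""
    c, s = math.cos(math.radians(deg)), math.sin(math.radians(deg))
    out = np.empty_like(np.asarray(points, dtype=float))
    for i, (x, y) in enumerate(points):
        dx, dy = x - centre[0], y - centre[1]
        out[i] = (centre[0] + c * dx - s * dy, centre[1] + s * dx + c * dy)
    return out


def angle_between_axes_oracle(fem_prox, fem_dist, tib_prox, tib_dist,
                              lateral_sign: int) -> float:
    """Signed aFTA recomputed directly from the four endpoint coordinates."""
    tf = math.degrees(math.atan2(fem_dist[0] - fem_prox[0],
                                 fem_dist[1] - fem_prox[1]))
    tt = math.degrees(math.atan2(tib_dist[0] - tib_prox[0],
                                 tib_dist[1] - tib_prox[1]))
    return lateral_sign * (tt - tf)
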