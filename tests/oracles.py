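"""Independent brute-force oracles used to check the fast estimators.

Everything here is written as literal loops over the defining formulas, kept
deliberately separate from the vectorised implementations they verify.
"""

import math

import numpy as np


def brute_pcf(points_i, points_j, window, r, bandwidth):
    """Literal double-loop bivariate pcf with Epanechnikov kernel and
    translation edge correction."""
    w, h = window.width, window.height
    area = window.area
    n_i, n_j = len(points_i), len(points_j)
    lam_i, lam_j = n_i / area, n_j / area
    total = 0.0
    for xi, yi in points_i:
        for xj, yj in points_j:
            dx, dy = xi - xj, yi - yj
            d = math.hypot(dx, dy)
            u = (d - r) / bandwidth
            if abs(u) < 1.0:
                k = 0.75 * (1.0 - u * u) / bandwidth
                total += k / ((w - abs(dx)) * (h - abs(dy)))
    return total / (2.0 * math.pi * r * lam_i * lam_j)


def brute_nn_fraction(points_i, points_j, r):
    """Empirical CDF of focal-to-other nearest-neighbour distances at r."""
    hits = 0
    for xi, yi in points_i:
        nnd = min(math.hypot(xi - xj, yi - yj) for xj, yj in points_j)
        if nnd <= r:
            hits += 1
    return hits / len(points_i)


def torus_distance_multiset(points, window):
    """Sorted multiset of all pairwise toroidal distances within a pattern."""
    w, h = window.width, window.height
    out = []
    n = len(points)
    for a in range(n):
        for b in range(a + 1, n):
            dx = abs(points[a][0] - points[b][0])
            dy = abs(points[a][1] - points[b][1])
            dx = min(dx, w - dx)
            dy = min(dy, h - dy)
            out.append(math.hypot(dx, dy))
    return np.sort(np.asarray(out))


def brute_pcf_univariate(points, window, r, bandwidth):
    """Within-pattern pcf (ordered pairs, self-pairs excluded)."""
    w, h = window.width, window.height
    area = window.area
    n = len(points)
    lam = n / area
    total = 0.0
    for a in range(n):
        for b in range(n):
            if a == b:
                continue
            dx = points[a][0] - points[b][0]
            dy = points[a][1] - points[b][1]
            d = math.hypot(dx, dy)
            u = (d - r) / bandwidth
            if abs(u) < 1.0:
                total += 0.75 * (1.0 - u * u) / bandwidth / ((w - abs(dx)) * (h - abs(dy)))
    # lambda^2 normalisation with the unbiased n(n-1) pair count
    return total / (2.0 * math.pi * r * lam * (n - 1) / area)


def quantile_linear(values, q):
    """Order-statistic quantile with linear interpolation (independent of numpy)."""
    xs = sorted(values)
    pos = (len(xs) - 1) * q
    lo = math.floor(pos)
    hi = math.ceil(pos)
    frac = pos - lo
    return xs[lo] * (1.0 - frac) + xs[hi] * frac
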