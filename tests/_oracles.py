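"""Independent brute-force oracles kept deliberately naive.

These re-derive the statistics from their definitions with plain double
loops, independent of the vectorized package code they are checked against.
"""

import numpy as np


def gi_star_brute(points, values, band):
    """Ord-Getis local Gi* from the definition, one focal point at a time."""
    points = np.asarray(points, dtype=float)
    values = np.asarray(values, dtype=float)
    n = len(values)
    xbar = sum(values) / n
    s = (sum((v - xbar) ** 2 for v in values) / n) ** 0.5
    z = np.empty(n)
    for i in range(n):
        w = [1.0 if np.hypot(*(points[i] - points[j])) <= band else 0.0
             for j in range(n)]
        wi = sum(w)
        sum_wx = sum(wij * xj for wij, xj in zip(w, values))
        sum_w2 = sum(wij ** 2 for wij in w)
        denom = s * ((n * sum_w2 - wi ** 2) / (n - 1)) ** 0.5
        # neighborhood covering all n points: 0/0, defined as 0
        z[i] = (sum_wx - xbar * wi) / denom if denom > 0 else 0.0
    return z


def semivariogram_brute(points, values, edges):
    """Matheron estimator by pair enumeration over given bin edges."""
    points = np.asarray(points, dtype=float)
    values = np.asarray(values, dtype=float)
    n = len(values)
    sums = np.zeros(len(edges) - 1)
    counts = np.zeros(len(edges) - 1, dtype=int)
    for i in range(n):
        for j in range(i + 1, n):
            d = float(np.hypot(*(points[i] - points[j])))
            if d == 0:
                continue
            for b in range(len(edges) - 1):
                if edges[b] < d <= edges[b + 1]:
                    sums[b] += (values[i] - values[j]) ** 2
                    counts[b] += 1
                    break
    gamma = np.where(counts > 0, sums / (2 * np.maximum(counts, 1)), np.nan)
    return gamma, counts


def durbin_watson_brute(e):
    return sum((e[i] - e[i - 1]) ** 2 for i in range(1, len(e))) / \
        sum(v ** 2 for v in e)
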