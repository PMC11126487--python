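"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own algorithms: the dip oracle solves
the defining minimax problem directly with linear programming, the interval
oracles count per-base membership, and the model-selection oracle enumerates
all subsets.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import linprog


def dip_oracle(values) -> float:
    """Dip statistic by direct minimisation over unimodal CDFs.

    For every candidate mode point m, a linear program finds the smallest
    band half-width d such that a nondecreasing function G in [0, 1] —
    convex over points 0..m, concave over points m..n-1 (the mode point is
    shared, so the slope chains run through it) — satisfies
    G(x_i) >= i/n - d and G(x_i) <= (i-1)/n + d (1-based ranks).  Requires a
    tie-free sample; the result is floored at 1/(2n).
    """
    x = np.sort(np.asarray(values, dtype=float))
    n = len(x)
    if len(np.unique(x)) != n:
        raise ValueError("dip LP oracle requires tie-free data")
    lower = (np.arange(1, n + 1)) / n  # F(x_i)
    upper = (np.arange(0, n)) / n      # F(x_i^-)

    best = np.inf
    for mode in range(n):  # points [0, mode] convex, [mode, n) concave
        # variables: g_0..g_{n-1}, d  -> minimise d
        c = np.zeros(n + 1)
        c[-1] = 1.0
        A_ub, b_ub = [], []

        def row():
            return np.zeros(n + 1)

        for i in range(n):
            r = row()           # lower_i - d <= g_i
            r[i], r[-1] = -1.0, -1.0
            A_ub.append(r)
            b_ub.append(-lower[i])
            r = row()           # g_i <= upper_i + d
            r[i], r[-1] = 1.0, -1.0
            A_ub.append(r)
            b_ub.append(upper[i])
        for i in range(n - 1):  # monotone
            r = row()
            r[i], r[i + 1] = 1.0, -1.0
            A_ub.append(r)
            b_ub.append(0.0)
        for part in ((0, mode + 1, 1.0), (mode, n, -1.0)):
            lo, hi, sign = part
            for j in range(lo + 1, hi - 1):
                dx1 = x[j] - x[j - 1]
                dx2 = x[j + 1] - x[j]
                # sign * (slope_right - slope_left) >= 0
                r = row()
                r[j - 1] = -sign * (1.0 / dx1)
                r[j] = sign * (1.0 / dx1 + 1.0 / dx2)
                r[j + 1] = -sign * (1.0 / dx2)
                A_ub.append(r)
                b_ub.append(0.0)
        bounds = [(0.0, 1.0)] * n + [(0.0, None)]
        res = linprog(c, A_ub=np.array(A_ub), b_ub=np.array(b_ub), bounds=bounds,
                      method="highs")
        if res.status == 0 and res.fun < best:
            best = res.fun
    return max(best, 1.0 / (2 * n))


def per_base_membership(intervals, length: int) -> np.ndarray:
    """Boolean occupancy of [0, length) from (start, end) pairs."""
    mask = np.zeros(length, dtype=bool)
    for s, e in intervals:
        mask[s:e] = True
    return mask


def best_subset_aic(candidates: dict, response: np.ndarray) -> tuple[frozenset, float]:
    """Exhaustive best-subset search under AIC = n*ln(RSS/n) + 2*(k+1)."""
    from itertools import combinations

    names = sorted(candidates)
    y = np.asarray(response, dtype=float)
    n = len(y)
    best_set, best_aic = frozenset(), np.inf
    for k in range(len(names) + 1):
        for combo in combinations(names, k):
            X = np.column_stack([np.ones(n)] + [candidates[c] for c in combo])
            beta, *_ = np.linalg.lstsq(X, y, rcond=None)
            rss = float(np.sum((y - X @ beta) ** 2))
            aic = n * np.log(max(rss, 1e-300) / n) + 2 * (len(combo) + 1)
            if aic < best_aic:
                best_set, best_aic = frozenset(combo), aic
    return best_set, best_aic


def welch_t_oracle(a, b) -> tuple[float, float]:
    """Textbook Welch t statistic and two-sided p via the t distribution."""
    from scipy import stats

    a = np.asarray(a, float)
    b = np.asarray(b, float)
    va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
    t = (a.mean() - b.mean()) / np.sqrt(va + vb)
    df = (va + vb) ** 2 / (va**2 / (len(a) - 1) + vb**2 / (len(b) - 1))
    p = 2 * stats.t.sf(abs(t), df)
    return float(t), float(p)
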