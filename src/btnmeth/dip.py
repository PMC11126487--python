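"""Hartigan & Hartigan's dip statistic and a Monte-Carlo dip test.

The dip of an empirical distribution function F_n is the smallest sup-norm
distance between F_n and the class of unimodal distribution functions
(convex below the mode, concave above it).  It is computed here with the
classical iterative scan: greatest convex minorant (GCM) and least concave
majorant (LCM) fits are alternated over a shrinking modal interval, and the
largest deviation found is halved.  The statistic is bounded below by
1/(2n) — the value attained by a sample of identical points.

The p-value is calibrated by Monte Carlo against samples from the uniform
distribution (the least favourable unimodal null), as in the original
proposal; a precomputed null table can be supplied to amortise the cost
over repeated tests at the same sample size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class DipResult:
    statistic: float
    p_value: float
    n: int
    n_boot: int
    seed: int | None


def dip_statistic(values) -> float:
    """Dip statistic of a 1-d sample (>= 1 observation)."""
    x = np.sort(np.asarray(values, dtype=float))
    n = len(x)
    if n < 1:
        raise ValueError("dip requires at least one observation")
    if n < 4 or x[0] == x[-1]:
        return 1.0 / (2 * n)

    # Convex-minorant predecessor pointers mn and concave-majorant successor
    # pointers mj over the whole sample (heights are the ranks).
    mn = np.zeros(n, dtype=np.int64)
    for j in range(1, n):
        mn[j] = j - 1
        while True:
            mnj = mn[j]
            mnmnj = mn[mnj]
            if mnj == 0 or (x[j] - x[mnj]) * (mnj - mnmnj) < (x[mnj] - x[mnmnj]) * (j - mnj):
                break
            mn[j] = mnmnj
    mj = np.zeros(n, dtype=np.int64)
    mj[n - 1] = n - 1
    for k in range(n - 2, -1, -1):
        mj[k] = k + 1
        while True:
            mjk = mj[k]
            mjmjk = mj[mjk]
            if mjk == n - 1 or (x[k] - x[mjk]) * (mjk - mjmjk) < (x[mjk] - x[mjmjk]) * (k - mjk):
                break
            mj[k] = mjmjk

    low, high = 0, n - 1
    dip = 1.0  # in rank units; divided by 2n at the end

    while True:
        if high <= low:  # modal interval collapsed; no further improvement
            break
        # GCM change points from high down to low, LCM from low up to high.
        gcm = [high]
        while gcm[-1] > low:
            gcm.append(int(mn[gcm[-1]]))
        lcm = [low]
        while lcm[-1] < high:
            lcm.append(int(mj[lcm[-1]]))
        icx, icv = len(gcm), len(lcm)

        # Largest distance between the GCM and LCM curves on [low, high].
        ix, iv = icx - 2, 1
        ig, ih = icx - 1, 0
        d = 0.0
        if icx != 2 or icv != 2:
            while True:
                gcmix, lcmiv = gcm[ix], lcm[iv]
                if gcmix > lcmiv:
                    # next change point comes from the LCM side
                    gcmi1 = gcm[ix + 1]
                    dx = (lcmiv - gcmi1 + 1) - (x[lcmiv] - x[gcmi1]) * (gcmix - gcmi1) / (
                        x[gcmix] - x[gcmi1]
                    )
                    iv += 1
                    if dx >= d:
                        d = dx
                        ig, ih = ix + 1, iv - 1
                else:
                    # next change point comes from the GCM side
                    lcmiv1 = lcm[iv - 1]
                    dx = (x[gcmix] - x[lcmiv1]) * (lcmiv - lcmiv1) / (
                        x[lcmiv] - x[lcmiv1]
                    ) - (gcmix - lcmiv1 - 1)
                    ix -= 1
                    if dx >= d:
                        d = dx
                        ig, ih = ix + 1, iv
                if ix < 0:
                    ix = 0
                if iv > icv - 1:
                    iv = icv - 1
                if gcm[ix] == lcm[iv]:
                    break
        else:
            d = 1.0
        if d < dip:
            break

        # Dip within the convex-minorant fit left of the new low candidate.
        dip_l = 0.0
        for j in range(ig, icx - 1):
            jb, je = gcm[j + 1], gcm[j]
            max_t = 1.0
            if je - jb > 1 and x[je] != x[jb]:
                c = (je - jb) / (x[je] - x[jb])
                for jj in range(jb, je + 1):
                    t = (jj - jb + 1) - (x[jj] - x[jb]) * c
                    if t > max_t:
                        max_t = t
            if dip_l < max_t:
                dip_l = max_t

        # Dip within the concave-majorant fit right of the new high candidate.
        dip_u = 0.0
        for j in range(ih, icv - 1):
            jb, je = lcm[j], lcm[j + 1]
            max_t = 1.0
            if je - jb > 1 and x[je] != x[jb]:
                c = (je - jb) / (x[je] - x[jb])
                for jj in range(jb, je + 1):
                    t = (x[jj] - x[jb]) * c - (jj - jb - 1)
                    if t > max_t:
                        max_t = t
            if dip_u < max_t:
                dip_u = max_t

        dip = max(dip, dip_l, dip_u)
        new_low, new_high = gcm[ig], lcm[ih]
        if new_low == low and new_high == high:
            break
        low, high = new_low, new_high

    return dip / (2 * n)


def dip_null_table(n: int, n_boot: int = 1000, seed: int | None = None,
                   rng: np.random.Generator | None = None) -> np.ndarray:
    """Monte-Carlo null distribution of the dip for uniform samples of size n."""
    rng = rng if rng is not None else np.random.default_rng(seed)
    return np.array([dip_statistic(rng.uniform(size=n)) for _ in range(n_boot)])


def dip_test(values, n_boot: int = 1000, seed: int | None = None,
             null_dips: np.ndarray | None = None) -> DipResult:
    """Dip test of unimodality with a Monte-Carlo uniform null.

    ``null_dips`` may carry a precomputed :func:`dip_null_table` for the same
    sample size, avoiding repeated bootstrap work across tests.
    """
    values = np.asarray(values, dtype=float)
    n = len(values)
    if n < 4:
        raise ValueError("dip test requires at least 4 observations")
    d = dip_statistic(values)
    if null_dips is None:
        null_dips = dip_null_table(n, n_boot, seed)
    p = float((np.sum(null_dips >= d) + 1) / (len(null_dips) + 1))
    return DipResult(statistic=d, p_value=p, n=n, n_boot=len(null_dips), seed=seed)
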