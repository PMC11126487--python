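"""Genome-wide and feature-wise 5mC/5hmC profiling.

The central summary is the 100-kb non-overlapping window: an unweighted mean
of per-CpG modification fractions plus the covariate fractions (gene parts,
repeats, CpG islands, GC and N content) that later feed the stepwise-AIC
predictor models.  Distribution comparisons use the two-sided Mann-Whitney U
test with the conventional significance-star legend; element-level profiles
are smoothed with 20-bp centred rolling windows.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .features import FeatureTrack, gc_n_content
from .io import GenomeSequence

#: p-value thresholds of the significance-star legend, most significant first
STAR_LEGEND = (
    (1.00e-4, "****"),
    (1.00e-3, "***"),
    (1.00e-2, "**"),
    (5.00e-2, "*"),
)


@dataclass(frozen=True)
class ComparisonResult:
    u_statistic: float
    p_value: float
    star: str
    n_a: int
    n_b: int
    method: str


@dataclass
class RollingProfile:
    positions: np.ndarray          # consensus coordinates with >=1 observation
    smoothed_mean: np.ndarray      # mean of per-copy smoothed values
    ci95_low: np.ndarray
    ci95_high: np.ndarray
    n_copies: int


@dataclass
class PerReadMatrix:
    matrix: pd.DataFrame           # read_id x site position, {1, 0, NaN}
    consistency_score: float       # fraction of sites with >=80% agreeing reads


# ---------------------------------------------------------------------------
# window profiling
# ---------------------------------------------------------------------------

def window_profile(
    calls: pd.DataFrame,
    genome: Sequence[GenomeSequence],
    tracks: Mapping[str, FeatureTrack] | None = None,
    window_size: int = 100_000,
) -> pd.DataFrame:
    """Per-window unweighted means of site fractions plus covariates.

    One row per non-overlapping window (terminal windows truncated); windows
    without CpG calls keep ``n_cpg == 0`` and undefined (NaN) means.
    """
    tracks = tracks or {}
    rows = []
    calls_by_contig = dict(tuple(calls.groupby("contig", observed=True)))
    for g in genome:
        length = len(g.sequence)
        sub = calls_by_contig.get(g.contig_id)
        for start in range(0, length, window_size):
            end = min(start + window_size, length)
            row = {"contig": g.contig_id, "start": start, "end": end}
            if sub is not None:
                inw = sub[(sub["pos"] >= start) & (sub["pos"] < end)]
                row["n_cpg"] = len(inw)
                row["mean_mc"] = float(inw["mc_frac"].mean()) if len(inw) else np.nan
                row["mean_hmc"] = float(inw["hmc_frac"].mean()) if len(inw) else np.nan
            else:
                row["n_cpg"], row["mean_mc"], row["mean_hmc"] = 0, np.nan, np.nan
            for name, track in tracks.items():
                row[f"{name}_frac"] = track.intersect_fraction((g.contig_id, start, end))
            gc, nf = gc_n_content(g.sequence, (start, end))
            row["gc_frac"], row["n_frac"] = gc, nf
            rows.append(row)
    return pd.DataFrame(rows)


def genome_summary(data, level: str = "window", channel: str = "mc") -> tuple[float, float]:
    """Genome-level (mean, sample SD) of a modification channel.

    ``level="window"`` summarises the defined window means of a window table
    (the headline genome figure); ``level="site"`` summarises raw site
    fractions of a call frame.  SD is undefined (NaN) below two values.
    """
    if level == "window":
        col = {"mc": "mean_mc", "hmc": "mean_hmc"}[channel]
        values = data[col].dropna().to_numpy()
    elif level == "site":
        col = {"mc": "mc_frac", "hmc": "hmc_frac"}[channel]
        values = data[col].to_numpy()
    else:
        raise ValueError(f"unknown level {level!r}")
    if len(values) == 0:
        return np.nan, np.nan
    mean = float(np.mean(values))
    sd = float(np.std(values, ddof=1)) if len(values) > 1 else np.nan
    return mean, sd


def feature_distribution(
    calls: pd.DataFrame,
    track: FeatureTrack,
    channel: str = "mc",
    min_cpg: int = 3,
) -> np.ndarray:
    """One mean methylation value per track interval with >= ``min_cpg`` sites.

    Intervals below the site threshold are excluded (avoids 0/1 spikes from
    one- or two-site intervals in the boxplot distributions).
    """
    col = {"mc": "mc_frac", "hmc": "hmc_frac"}[channel]
    values = []
    for contig, sub in calls.groupby("contig", observed=True):
        pos = sub["pos"].to_numpy()
        frac = sub[col].to_numpy()
        order = np.argsort(pos)
        pos, frac = pos[order], frac[order]
        for s, e, _, _ in track.by_contig.get(contig, []):
            lo, hi = np.searchsorted(pos, [s, e])
            if hi - lo >= min_cpg:
                values.append(float(frac[lo:hi].mean()))
    return np.asarray(values)


# ---------------------------------------------------------------------------
# distribution comparison
# ---------------------------------------------------------------------------

def star_annotation(p: float) -> str:
    """Map a p-value to the significance-star legend used in the figures."""
    for threshold, star in STAR_LEGEND:
        if p <= threshold:
            return star
    return "ns"


def compare_distributions(a, b, exact_limit: int = 400) -> ComparisonResult:
    """Two-sided Mann-Whitney U comparison of two value distributions.

    Uses exact enumeration when ``n_a * n_b <= exact_limit`` and the pooled
    sample is tie-free, otherwise the tie-corrected normal approximation
    (with continuity correction).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must contain at least one value")
    pooled = np.concatenate([a, b])
    tie_free = len(np.unique(pooled)) == len(pooled)
    method = "exact" if (len(a) * len(b) <= exact_limit and tie_free) else "asymptotic"
    if np.ptp(pooled) == 0:
        # identical constant samples: no evidence against exchangeability
        return ComparisonResult(len(a) * len(b) / 2, 1.0, "ns", len(a), len(b), "degenerate")
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    p = float(min(res.pvalue, 1.0))
    return ComparisonResult(float(res.statistic), p, star_annotation(p), len(a), len(b), method)


def exact_mannwhitney_p(a, b) -> float:
    """Brute-force two-sided Mann-Whitney p by enumeration of arrangements.

    Independent oracle for small tie-free samples: enumerates all
    C(n_a+n_b, n_a) assignments of the pooled ranks.
    """
    from itertools import combinations

    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    pooled = np.sort(np.concatenate([a, b]))
    if len(np.unique(pooled)) != len(pooled):
        raise ValueError("exact enumeration oracle requires tie-free data")
    n_a, n = len(a), len(pooled)
    ranks = np.arange(1, n + 1)
    u_obs = stats.rankdata(np.concatenate([a, b]))[:n_a].sum() - n_a * (n_a + 1) / 2
    u_lo, u_hi = min(u_obs, n_a * (n - n_a) - u_obs), max(u_obs, n_a * (n - n_a) - u_obs)
    count = total = 0
    for combo in combinations(range(n), n_a):
        u = ranks[list(combo)].sum() - n_a * (n_a + 1) / 2
        total += 1
        if u <= u_lo or u >= u_hi:
            count += 1
    return count / total


# ---------------------------------------------------------------------------
# element-level profiles
# ---------------------------------------------------------------------------

def rolling_element_profile(
    copy_profiles: Mapping[str, tuple[np.ndarray, np.ndarray]],
    window: int = 20,
) -> RollingProfile:
    """Smoothed consensus-coordinate methylation profile across element copies.

    ``copy_profiles`` maps copy id to ``(consensus_positions, fractions)``.
    Each copy is smoothed with a centred ``window``-bp rolling average over
    its own sites (edge windows truncated, no padding); the cross-copy mean
    and a 95% confidence band (t-interval below 30 copies, normal otherwise)
    are reported at every consensus position observed in any copy.
    """
    if not copy_profiles:
        raise ValueError("at least one copy profile is required")
    half = window / 2
    all_pos = np.unique(np.concatenate([np.asarray(p) for p, _ in copy_profiles.values()]))
    per_copy = np.full((len(copy_profiles), len(all_pos)), np.nan)
    for row, (pos, frac) in enumerate(copy_profiles.values()):
        pos = np.asarray(pos, dtype=float)
        frac = np.asarray(frac, dtype=float)
        order = np.argsort(pos)
        pos, frac = pos[order], frac[order]
        cum = np.concatenate([[0.0], np.cumsum(frac)])
        # centred half-open window [p - w/2, p + w/2)
        lo = np.searchsorted(pos, all_pos - half, side="left")
        hi = np.searchsorted(pos, all_pos + half, side="left")
        counts = hi - lo
        with np.errstate(invalid="ignore"):
            sm = np.where(counts > 0, (cum[hi] - cum[lo]) / np.maximum(counts, 1), np.nan)
        per_copy[row] = sm
    n_obs = np.sum(~np.isnan(per_copy), axis=0)
    mean = np.nanmean(np.where(n_obs > 0, per_copy, np.nan), axis=0)
    sd = np.full(len(all_pos), np.nan)
    multi = n_obs > 1
    sd[multi] = np.nanstd(per_copy[:, multi], axis=0, ddof=1)
    n = len(copy_profiles)
    crit = stats.t.ppf(0.975, n - 1) if 1 < n < 30 else stats.norm.ppf(0.975)
    with np.errstate(invalid="ignore"):
        half_width = np.where(n_obs > 1, crit * sd / np.sqrt(np.maximum(n_obs, 1)), np.nan)
    return RollingProfile(
        positions=all_pos,
        smoothed_mean=mean,
        ci95_low=mean - half_width,
        ci95_high=mean + half_width,
        n_copies=n,
    )


def per_read_matrix(read_calls: pd.DataFrame, agreement: float = 0.8) -> PerReadMatrix:
    """Read x CpG-site methylation-state matrix for one locus.

    ``read_calls`` needs columns ``read_id``, ``pos`` and ``state`` (1 =
    methylated, 0 = unmethylated; absent combinations are missing).  The
    consistency score is the fraction of sites at which at least
    ``agreement`` of the observing reads share the majority state.
    """
    matrix = read_calls.pivot_table(index="read_id", columns="pos", values="state",
                                    aggfunc="first")
    consistent = 0
    n_sites = matrix.shape[1]
    for pos in matrix.columns:
        col = matrix[pos].dropna()
        if len(col) == 0:
            n_sites -= 1
            continue
        top = col.value_counts().iloc[0]
        if top / len(col) >= agreement:
            consistent += 1
    score = consistent / n_sites if n_sites else float("nan")
    return PerReadMatrix(matrix=matrix, consistency_score=score)
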