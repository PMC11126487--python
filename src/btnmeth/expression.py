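"""TPM normalisation and methylation-expression coupling.

Expression is length-normalised to transcripts per million; the coupling
statistic is the Pearson correlation between each gene's proportion of
methylated intragenic CpGs and its log10(TPM + 1) expression.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .features import FeatureTrack


def tpm(counts, effective_lengths) -> np.ndarray:
    """Transcripts per million from raw counts and effective lengths.

    ``rate_g = count_g / length_g``; ``tpm_g = rate_g / sum(rate) * 1e6``.
    Invariant under uniform scaling of the counts; sums to 1e6.
    """
    counts = np.asarray(counts, dtype=float)
    lengths = np.asarray(effective_lengths, dtype=float)
    if (lengths <= 0).any():
        raise ValueError("effective lengths must be positive")
    if counts.sum() == 0:
        raise ValueError("all-zero count vector")
    rate = counts / lengths
    return rate / rate.sum() * 1e6


def tpm_table(expr: pd.DataFrame) -> pd.DataFrame:
    out = expr.copy()
    out["tpm"] = tpm(expr["count"], expr["effective_length"])
    return out


def methylated_cpg_proportion(
    calls: pd.DataFrame,
    gene_track: FeatureTrack,
    threshold: float = 0.5,
    min_cpg: int = 3,
) -> pd.Series:
    """Per-gene fraction of intragenic CpG sites with mC fraction >= threshold."""
    props: dict[str, float] = {}
    by_contig = dict(tuple(calls.groupby("contig", observed=True)))
    for contig, start, end, _, name in gene_track.iter_intervals():
        sub = by_contig.get(contig)
        if sub is None:
            continue
        pos = sub["pos"].to_numpy()
        lo, hi = np.searchsorted(pos, [start, end])
        if hi - lo >= min_cpg:
            props[name] = float((sub["mc_frac"].to_numpy()[lo:hi] >= threshold).mean())
    return pd.Series(props, name="methylated_cpg_proportion")


@dataclass(frozen=True)
class CorrelationResult:
    pearson_r: float
    p_value: float
    n: int


def methylation_expression_correlation(
    methylation: pd.Series | Mapping[str, float],
    expression_tpm: pd.Series | Mapping[str, float],
    log_transform: bool = True,
) -> CorrelationResult:
    """Pearson correlation between gene methylation and expression.

    Expression is taken as log10(TPM + 1) unless ``log_transform`` is
    disabled; only genes present in both tables enter.  The p-value is the
    two-sided t-distribution test of r.
    """
    meth = pd.Series(methylation).dropna()
    expr = pd.Series(expression_tpm).dropna()
    genes = meth.index.intersection(expr.index)
    if len(genes) < 3:
        raise ValueError("need at least 3 genes present in both tables")
    x = meth.loc[genes].to_numpy(dtype=float)
    y = expr.loc[genes].to_numpy(dtype=float)
    if log_transform:
        y = np.log10(y + 1.0)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in methylation or expression")
    r, p = stats.pearsonr(x, y)
    return CorrelationResult(pearson_r=float(r), p_value=float(p), n=len(genes))
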