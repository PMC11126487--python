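"""Standalone retroelement copy-set simulation under a two-epoch model.

Healthy-genome copies descend from a pre-split ancestor (shared mutations),
while each tumour copy diverges privately from the consensus — the regime
in which a copy phylogeny shows a distinct healthy-only cluster with the
two tumour lineages intermingled.  The model-implied expected pairwise
distances (sums of branch substitution rates) are emitted alongside the
sequences so estimator tests recover parameters rather than refit noise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ..te import TEConsensus
from .consensus import mutate


@dataclass
class SimulatedCopySet:
    labels: list            # e.g. healthy_1, cedbtn1_3 ...
    sequences: dict         # label -> sequence (all equal length, gap-free)
    true_distances: pd.DataFrame   # expected pairwise distances (branch sums)
    lineages: dict          # label -> lineage name


def simulate_te_copies(
    consensus: TEConsensus,
    n_per_lineage: dict,
    seed: int,
    shared_divergence: float = 0.05,
    healthy_private: float = 0.01,
    tumour_private: float = 0.02,
) -> SimulatedCopySet:
    """Evolve element copies for each lineage.

    ``n_per_lineage`` maps lineage name (``healthy`` plus any tumour
    lineages) to copy count.  Healthy copies share ``shared_divergence``
    from the pre-split ancestor plus a private branch; tumour copies carry
    only private divergence from the consensus.
    """
    if not n_per_lineage or min(n_per_lineage.values()) < 1:
        raise ValueError("every lineage needs at least one copy")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 606]))
    labels, seqs, lineages = [], {}, {}
    branch: dict[str, float] = {}      # private branch length per copy
    is_healthy: dict[str, bool] = {}

    ancestor = mutate(consensus.sequence, shared_divergence, rng)
    for lineage, n in sorted(n_per_lineage.items()):
        healthy = lineage == "healthy"
        base = ancestor if healthy else consensus.sequence
        rate = healthy_private if healthy else tumour_private
        for i in range(n):
            label = f"{lineage}_{i + 1}"
            labels.append(label)
            seqs[label] = mutate(base, rate, rng)
            lineages[label] = lineage
            branch[label] = rate
            is_healthy[label] = healthy

    D = np.zeros((len(labels), len(labels)))
    for i, a in enumerate(labels):
        for j, b in enumerate(labels):
            if i == j:
                continue
            d = branch[a] + branch[b]
            if is_healthy[a] != is_healthy[b]:
                d += shared_divergence
            D[i, j] = d
    return SimulatedCopySet(
        labels=labels,
        sequences=seqs,
        true_distances=pd.DataFrame(D, index=labels, columns=labels),
        lineages=lineages,
    )
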