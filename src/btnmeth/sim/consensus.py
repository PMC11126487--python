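"""Deterministic reference sequences for the simulator.

The two retroelement consensus sequences (a ~7.5 kb element with four ORFs
and an internal 61-bp direct repeat, and a 6.2 kb LINE-like element with a
single long ORF), the satellite monomer and the tandem-repeat monomer are
generated once from a fixed internal seed, independent of any user seed, so
every preset and every run sees identical reference sequences.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np

from ..te import TEConsensus

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

#: internal constant; never derived from a user seed
_REFERENCE_SEED = 20240717

CEDCL34_LENGTH = 7500
CEDCL24_LENGTH = 6200
SATELLITE_MONOMER_LENGTH = 330
TANDEM_MONOMER_LENGTH = 150


def random_dna(rng: np.random.Generator, length: int, gc: float = 0.42) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return _BASES[rng.choice(4, size=length, p=p)].tobytes().decode()


def cpg_rich_dna(rng: np.random.Generator, length: int, cpg_rate: float = 0.22,
                 gc: float = 0.60) -> str:
    """CpG-dense sequence: emits CG dinucleotides at ``cpg_rate`` per step."""
    out = []
    n = 0
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    while n < length:
        if rng.random() < cpg_rate:
            out.append("CG")
            n += 2
        else:
            out.append(_BASES[rng.choice(4, p=p)].tobytes().decode())
            n += 1
    return "".join(out)[:length]


def _with_cpgs(rng: np.random.Generator, length: int, n_cpg: int, gc: float) -> str:
    """Random sequence with roughly ``n_cpg`` planted CG dinucleotides."""
    seq = list(random_dna(rng, length, gc))
    pos = rng.choice(np.arange(0, length - 2, 2), size=n_cpg, replace=False)
    for p in sorted(pos):
        seq[p], seq[p + 1] = "C", "G"
    return "".join(seq)


@lru_cache(maxsize=1)
def consensus_elements() -> dict[str, TEConsensus]:
    """The two retroelement consensus sequences, keyed by family name."""
    rng = np.random.default_rng(_REFERENCE_SEED)
    # CedCL34-like: two segments split by an internal 61-bp direct repeat
    direct_repeat = random_dna(rng, 61, gc=0.45)
    seg1 = random_dna(rng, 3600, gc=0.43)
    seg2 = random_dna(rng, CEDCL34_LENGTH - 2 * 61 - 3600, gc=0.43)
    cl34_seq = seg1 + direct_repeat + seg2 + direct_repeat
    cl34 = TEConsensus(
        name="CedCL34",
        sequence=cl34_seq[:CEDCL34_LENGTH],
        orf_intervals=(
            (150, 1100, "ORF1"),
            (1200, 2900, "ORF2"),
            (3800, 5300, "ORF3_integrase"),
            (5400, 7300, "ORF4_RT"),
        ),
    )
    cl24 = TEConsensus(
        name="CedCL24",
        sequence=random_dna(rng, CEDCL24_LENGTH, gc=0.41),
        orf_intervals=(
            (200, 900, "ORF1"),
            (1000, 5800, "ORF2_endo_RT_RH"),
        ),
    )
    return {"CedCL34": cl34, "CedCL24": cl24}


@lru_cache(maxsize=1)
def satellite_monomer() -> str:
    rng = np.random.default_rng(_REFERENCE_SEED + 1)
    return _with_cpgs(rng, SATELLITE_MONOMER_LENGTH, n_cpg=8, gc=0.38)


@lru_cache(maxsize=1)
def tandem_monomer() -> str:
    rng = np.random.default_rng(_REFERENCE_SEED + 2)
    return _with_cpgs(rng, TANDEM_MONOMER_LENGTH, n_cpg=5, gc=0.48)


def mutate(seq: str, rate: float, rng: np.random.Generator,
           transition_weight: float = 2.0) -> str:
    """Point-substitute a sequence at the given per-base rate (no indels).

    Transitions outweigh transversions ``transition_weight``:1, matching the
    two-parameter substitution model used for the divergence estimates.
    """
    if rate <= 0:
        return seq
    transition = {"A": "G", "G": "A", "C": "T", "T": "C"}
    transversions = {"A": "CT", "G": "CT", "C": "AG", "T": "AG"}
    arr = list(seq)
    hit = np.flatnonzero(rng.random(len(arr)) < rate)
    p_ts = transition_weight / (transition_weight + 1.0)
    for i in hit:
        base = arr[i]
        if base not in "ACGT":
            continue
        if rng.random() < p_ts:
            arr[i] = transition[base]
        else:
            arr[i] = transversions[base][rng.integers(2)]
    return "".join(arr)
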