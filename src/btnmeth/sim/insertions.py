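"""Structural-variant insertion callset simulation.

Plants the preset's true retroelement insertions — records that survive the
whole support / PASS / PRECISE / consensus-match filter chain, composed of
consensus fragments, full-length elements and head-to-tail dimers — plus
decoy records failing each filter for exactly one reason.
"""

from __future__ import annotations

import numpy as np

from ..io import InsertionCall
from .consensus import consensus_elements, mutate, random_dna
from .genome import SimulatedGenome
from .presets import LineagePreset


def _true_seq(kind, cons_seq: str, rng) -> str:
    if kind == "full":
        return mutate(cons_seq, 0.01, rng)
    if kind == "dimer":
        return mutate(cons_seq, 0.01, rng) + mutate(cons_seq, 0.01, rng)
    # fragment: contiguous consensus span of 1-3 kb (>= the 200 bp match gate)
    ln = int(rng.integers(1000, min(3000, len(cons_seq) - 1)))
    start = int(rng.integers(0, len(cons_seq) - ln))
    return mutate(cons_seq[start:start + ln], 0.01, rng)


def simulate_insertion_callset(
    sg: SimulatedGenome,
    preset: LineagePreset,
    seed: int,
) -> list[InsertionCall]:
    """Insertion records for one lineage, true calls plus planted decoys."""
    plan = preset.insertion_plan
    if plan is None:
        raise ValueError(f"preset {preset.name} has no insertion plan")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 505]))
    consensus = consensus_elements()
    lengths = sg.contig_lengths
    contigs = list(lengths)

    def random_locus():
        c = contigs[int(rng.integers(len(contigs)))]
        return c, int(rng.integers(1000, lengths[c] - 1000))

    calls: list[InsertionCall] = []
    serial = 0

    def add(seq, support, flags, precise, svtype="INS", rid_prefix="ins"):
        nonlocal serial
        contig, pos = random_locus()
        serial += 1
        calls.append(InsertionCall(
            contig=contig, pos=pos, svtype=svtype, length=len(seq),
            support=support, filter_flags=frozenset(flags), precise=precise,
            inserted_seq=seq, record_id=f"{rid_prefix}_{serial}"))

    # true insertions per family, per the planned composition
    for family, count in plan.true_counts.items():
        comp = dict(plan.composition.get(family, ()))
        kinds = ([k for k, n in comp.items() for _ in range(n)]
                 or ["fragment"] * count)
        if len(kinds) != count:
            raise ValueError(f"composition for {family} does not sum to {count}")
        for kind in kinds:
            add(_true_seq(kind, consensus[family].sequence, rng),
                support=int(rng.integers(4, 25)), flags=("PASS",), precise=True,
                rid_prefix=f"{family}_{kind}")

    # decoys: each fails the chain for exactly one documented reason
    cl34 = consensus["CedCL34"].sequence
    for _ in range(plan.decoys_per_reason):
        good = mutate(cl34[:2500], 0.01, rng)
        add(good, support=3, flags=("PASS",), precise=True, rid_prefix="decoy_support")
        add(good, support=10, flags=("GT",), precise=True, rid_prefix="decoy_filter")
        add(good, support=10, flags=("PASS",), precise=False, rid_prefix="decoy_imprecise")
        add(random_dna(rng, 2500), support=10, flags=("PASS",), precise=True,
            rid_prefix="decoy_nomatch")
        add(mutate(cl34[:150], 0.01, rng), support=10, flags=("PASS",), precise=True,
            rid_prefix="decoy_short")
        add(mutate(cl34[:1500], 0.30, rng), support=10, flags=("PASS",), precise=True,
            rid_prefix="decoy_lowid")
        add(good, support=10, flags=("PASS",), precise=True, svtype="DEL",
            rid_prefix="decoy_svtype")
    return calls
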