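"""Retrotransposon workflow: copy discovery, divergence, phylogeny, insertions.

Copies of a consensus element are recovered from a genome with exact k-mer
seeding followed by alignment extension; per-copy Kimura two-parameter
distances to the consensus are binned into a divergence landscape; copy
phylogenies use the Saitou-Nei neighbour-joining agglomeration; long-read
insertion callsets run through the support / PASS / PRECISE / consensus-match
filter chain with head-to-tail tandem counting; and element-level CpG
methylation is summarised by projecting site calls onto consensus
coordinates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import edlib
import numpy as np
import pandas as pd

from .features import enumerate_cpg_sites
from .io import GenomeSequence, InsertionCall

logger = logging.getLogger(__name__)

_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass
class TEConsensus:
    name: str
    sequence: str
    orf_intervals: tuple = ()     # ((start, end, label), ...)

    def __post_init__(self):
        for s, e, label in self.orf_intervals:
            if not (0 <= s < e <= len(self.sequence)):
                raise ValueError(f"ORF {label} outside consensus bounds")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class TECopy:
    contig: str
    start: int
    end: int
    strand: str
    aligned_identity: float
    coverage_of_consensus: float
    is_full_length: bool
    consensus_start: int
    consensus_end: int
    sequence: str = ""
    copy_id: str = ""


# ---------------------------------------------------------------------------
# k-mer seeded scanning
# ---------------------------------------------------------------------------

_BASE_CODE = np.full(256, 5, dtype=np.int64)
for _i, _b in enumerate("ACGT"):
    _BASE_CODE[ord(_b)] = _i


def _encode(seq: str) -> np.ndarray:
    return _BASE_CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]


def _kmer_codes(codes: np.ndarray, k: int) -> np.ndarray:
    """Rolling k-mer integer codes; windows touching non-ACGT bases get -1."""
    n = len(codes) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    out = np.zeros(n, dtype=np.int64)
    bad = np.zeros(n, dtype=bool)
    for j in range(k):
        win = codes[j:j + n]
        out = out * 4 + np.where(win > 3, 0, win)
        bad |= win > 3
    out[bad] = -1
    return out


def _seed_hits(query_codes: np.ndarray, target_codes: np.ndarray):
    """(target_pos, query_pos) pairs of exact shared k-mers."""
    valid_q = np.flatnonzero(query_codes >= 0)
    order = np.argsort(query_codes[valid_q], kind="stable")
    sorted_codes = query_codes[valid_q][order]
    sorted_qpos = valid_q[order]
    t_valid = np.flatnonzero(target_codes >= 0)
    idx_lo = np.searchsorted(sorted_codes, target_codes[t_valid], side="left")
    idx_hi = np.searchsorted(sorted_codes, target_codes[t_valid], side="right")
    hit_mask = idx_hi > idx_lo
    t_hits, lo_hits, hi_hits = t_valid[hit_mask], idx_lo[hit_mask], idx_hi[hit_mask]
    tpos, qpos = [], []
    for t, lo, hi in zip(t_hits, lo_hits, hi_hits):
        for j in range(lo, hi):
            tpos.append(t)
            qpos.append(sorted_qpos[j])
    return np.array(tpos, dtype=np.int64), np.array(qpos, dtype=np.int64)


def _chain_seeds(tpos, qpos, k, max_gap=500, diag_slack=60, min_seeds=3, min_span=100):
    """Greedy chaining of co-diagonal seeds into candidate loci."""
    if len(tpos) == 0:
        return []
    diag = tpos - qpos
    order = np.lexsort((tpos, diag // diag_slack))
    chains = []
    cur = None
    for i in order:
        t, q, dg = int(tpos[i]), int(qpos[i]), int(diag[i])
        if (cur is not None and abs(dg - cur["diag"]) <= diag_slack
                and 0 <= t - cur["t_hi"] <= max_gap):
            cur["t_hi"], cur["q_hi"] = max(cur["t_hi"], t), max(cur["q_hi"], q)
            cur["q_lo"] = min(cur["q_lo"], q)
            cur["n"] += 1
        else:
            if cur is not None:
                chains.append(cur)
            cur = {"t_lo": t, "t_hi": t, "q_lo": q, "q_hi": q, "diag": dg, "n": 1}
    chains.append(cur)
    out = []
    for c in chains:
        span = c["t_hi"] + k - c["t_lo"]
        if c["n"] >= min_seeds and span >= min_span:
            out.append((c["q_lo"], c["q_hi"] + k, c["t_lo"], c["t_hi"] + k))
    return out


def local_matches(
    consensus_seq: str,
    target_seq: str,
    min_id: float = 0.80,
    min_len: int = 200,
    k: int = 12,
    flank: int = 25,
) -> list[dict]:
    """Local alignments of a consensus element within a target sequence.

    Returns dicts with target ``start``/``end``, ``strand``, consensus
    ``q_start``/``q_end`` and ``identity``.  Seeds are exact 12-mers chained
    by diagonal; each chained candidate is polished with an infix (edlib
    "HW") alignment of the chained consensus span plus a small flank.
    """
    t_codes = _kmer_codes(_encode(target_seq), k)
    hits = []
    L = len(consensus_seq)
    for strand, qseq in (("+", consensus_seq), ("-", revcomp(consensus_seq))):
        q_codes = _kmer_codes(_encode(qseq), k)
        tpos, qpos = _seed_hits(q_codes, t_codes)
        for q_lo, q_hi, t_lo, t_hi in _chain_seeds(tpos, qpos, k):
            q_lo = max(0, q_lo - flank)
            q_hi = min(L, q_hi + flank)
            seg_lo = max(0, t_lo - (flank + 30))
            seg_hi = min(len(target_seq), t_hi + flank + 30)
            query = qseq[q_lo:q_hi]
            if len(query) < min_len or seg_hi - seg_lo < len(query) // 2:
                continue
            aln = edlib.align(query, target_seq[seg_lo:seg_hi], mode="HW", task="locations")
            if aln["editDistance"] < 0 or not aln["locations"]:
                continue
            loc = aln["locations"][0]
            identity = 1.0 - aln["editDistance"] / len(query)
            if identity < min_id:
                continue
            t_start, t_end = seg_lo + loc[0], seg_lo + loc[1] + 1
            if strand == "+":
                c_start, c_end = q_lo, q_hi
            else:
                c_start, c_end = L - q_hi, L - q_lo
            hits.append(
                {
                    "start": int(t_start), "end": int(t_end), "strand": strand,
                    "q_start": int(c_start), "q_end": int(c_end),
                    "identity": float(identity),
                }
            )
    # merge overlapping hits on the same strand, keeping the widest evidence
    merged: list[dict] = []
    for h in sorted(hits, key=lambda h: (h["strand"], h["start"], h["end"])):
        last = merged[-1] if merged else None
        if last and last["strand"] == h["strand"] and h["start"] < last["end"]:
            last["end"] = max(last["end"], h["end"])
            last["q_start"] = min(last["q_start"], h["q_start"])
            last["q_end"] = max(last["q_end"], h["q_end"])
            last["identity"] = max(last["identity"], h["identity"])
        else:
            merged.append(dict(h))
    return merged


def scan_copies(
    genome: Sequence[GenomeSequence],
    consensus: TEConsensus,
    min_id: float = 0.80,
    full_cov: float = 0.90,
    min_len: int = 200,
) -> list[TECopy]:
    """Recover copies of a consensus element from a genome.

    A copy is full-length when its consensus coverage reaches ``full_cov``
    at identity >= ``min_id``.
    """
    if len(consensus) < 100:
        raise ValueError("consensus shorter than 100 bp")
    copies = []
    for g in genome:
        for h in local_matches(consensus.sequence, g.sequence, min_id, min_len):
            coverage = (h["q_end"] - h["q_start"]) / len(consensus)
            seq = g.sequence[h["start"]:h["end"]]
            if h["strand"] == "-":
                seq = revcomp(seq)
            copies.append(
                TECopy(
                    contig=g.contig_id, start=h["start"], end=h["end"],
                    strand=h["strand"], aligned_identity=h["identity"],
                    coverage_of_consensus=float(coverage),
                    is_full_length=bool(coverage >= full_cov and h["identity"] >= min_id),
                    consensus_start=h["q_start"], consensus_end=h["q_end"],
                    sequence=seq,
                    copy_id=f"{consensus.name}_{g.contig_id}_{h['start']}",
                )
            )
    return copies


# ---------------------------------------------------------------------------
# Kimura two-parameter distance and divergence landscapes
# ---------------------------------------------------------------------------

_PURINES = frozenset("AG")
_PYRIMIDINES = frozenset("CT")


def kimura_distance(a: str, b: str) -> float:
    """Kimura 2-parameter distance between two equal-length aligned strings.

    ``d = -1/2 * ln((1 - 2P - Q) * sqrt(1 - 2Q))`` with P and Q the
    transition and transversion proportions over ungapped, unambiguous
    columns.  Saturated pairs (log argument <= 0) return ``inf``.
    """
    if len(a) != len(b):
        raise ValueError("aligned sequences must have equal length")
    a, b = a.upper(), b.upper()
    valid = transitions = transversions = 0
    for ca, cb in zip(a, b):
        if ca in "-N" or cb in "-N":
            continue
        valid += 1
        if ca == cb:
            continue
        same_class = (ca in _PURINES) == (cb in _PURINES)
        if same_class:
            transitions += 1
        else:
            transversions += 1
    if valid == 0:
        raise ValueError("no ungapped comparable columns")
    P, Q = transitions / valid, transversions / valid
    arg = (1 - 2 * P - Q) * np.sqrt(max(1 - 2 * Q, 0.0))
    if arg <= 0:
        logger.warning("saturated K2P pair (P=%.3f, Q=%.3f)", P, Q)
        return float("inf")
    return float(-0.5 * np.log(arg))


def aligned_pair(a: str, b: str) -> tuple[str, str]:
    """Global (NW) alignment of two sequences via edlib, as gapped strings."""
    res = edlib.align(a, b, mode="NW", task="path")
    nice = edlib.getNiceAlignment(res, a, b)
    return nice["query_aligned"], nice["target_aligned"]


@dataclass
class DivergenceLandscape:
    bin_edges: np.ndarray         # 0..0.50 in 1% steps
    coverage_percent: np.ndarray  # per-bin genome coverage, percent
    total_percent: float
    n_copies: int


def divergence_landscape(
    copies: Sequence[TECopy],
    consensus: TEConsensus,
    genome_size: int,
    bin_width: float = 0.01,
    max_div: float = 0.50,
) -> DivergenceLandscape:
    """Genome coverage of element copies binned by K2P distance to consensus.

    Each copy's bases are assigned to the bin of its distance from the
    matching consensus span; coverage is percent of the genome.  Saturated
    copies land in the last bin.
    """
    edges = np.arange(0, max_div + bin_width / 2, bin_width)
    cov = np.zeros(len(edges) - 1)
    for c in copies:
        ref = consensus.sequence[c.consensus_start:c.consensus_end]
        qa, qb = (c.sequence, ref) if len(c.sequence) == len(ref) else aligned_pair(c.sequence, ref)
        d = kimura_distance(qa, qb)
        b = min(int(min(d, max_div - 1e-9) / bin_width), len(cov) - 1)
        cov[b] += c.end - c.start
    cov = cov / genome_size * 100.0
    return DivergenceLandscape(
        bin_edges=edges,
        coverage_percent=cov,
        total_percent=float(cov.sum()),
        n_copies=len(copies),
    )


# ---------------------------------------------------------------------------
# neighbour joining
# ---------------------------------------------------------------------------

def nj_tree(distance_matrix, labels: Sequence[str]) -> str:
    """Saitou-Nei neighbour joining, returned as a newick string.

    Uses the Studier-Keppler Q criterion with a deterministic lowest-index
    tie-break; negative branch lengths are clamped to zero with a warning.
    """
    D = np.array(distance_matrix, dtype=float)
    n = D.shape[0]
    if D.shape != (n, n) or n < 3:
        raise ValueError("need a square matrix over at least 3 taxa")
    if np.isnan(D).any():
        raise ValueError("distance matrix contains NaN")
    if not np.allclose(D, D.T) or not np.allclose(np.diag(D), 0):
        raise ValueError("matrix must be symmetric with zero diagonal")
    if len(labels) != n:
        raise ValueError("labels do not match matrix size")

    def branch(length: float) -> float:
        if length < 0:
            if length < -1e-9:
                logger.warning("negative NJ branch length %.4g clamped to 0", length)
            return 0.0
        return length

    nodes = [str(l) for l in labels]
    active = list(range(n))
    D = D.copy()
    while len(active) > 3:
        m = len(active)
        r = {i: sum(D[i, j] for j in active if j != i) for i in active}
        best = None
        for ai in range(m):
            for aj in range(ai + 1, m):
                i, j = active[ai], active[aj]
                q = (m - 2) * D[i, j] - r[i] - r[j]
                if best is None or q < best[0] - 1e-12:
                    best = (q, i, j)
        _, i, j = best
        vi = 0.5 * D[i, j] + (r[i] - r[j]) / (2 * (m - 2))
        vj = D[i, j] - vi
        new = f"({nodes[i]}:{branch(vi):.10g},{nodes[j]}:{branch(vj):.10g})"
        # grow the matrix with the merged node
        drow = np.zeros(D.shape[0] + 1)
        for kk in active:
            if kk not in (i, j):
                drow[kk] = 0.5 * (D[i, kk] + D[j, kk] - D[i, j])
        D = np.pad(D, ((0, 1), (0, 1)))
        D[-1, :-1] = drow[:-1]
        D[:-1, -1] = drow[:-1]
        nodes.append(new)
        active = [a for a in active if a not in (i, j)] + [D.shape[0] - 1]
    a, b, c = active
    va = branch(0.5 * (D[a, b] + D[a, c] - D[b, c]))
    vb = branch(0.5 * (D[a, b] + D[b, c] - D[a, c]))
    vc = branch(0.5 * (D[a, c] + D[b, c] - D[a, b]))
    return f"({nodes[a]}:{va:.10g},{nodes[b]}:{vb:.10g},{nodes[c]}:{vc:.10g});"


# ---------------------------------------------------------------------------
# insertion filter chain
# ---------------------------------------------------------------------------

@dataclass
class KeptInsertion:
    call: InsertionCall
    family: str
    tandem_count: int
    needs_validation: bool


@dataclass
class FilteredInsertionSet:
    kept: list
    rejected: list                # (InsertionCall, first-failing reason)

    def kept_by_family(self, family: str) -> list:
        return [k for k in self.kept if k.family == family]


#: first-failing rejection reasons, in documented precedence order
REJECTION_ORDER = ("svtype", "support", "filter", "precision", "no_consensus_match")


def filter_insertions(
    calls: Iterable[InsertionCall],
    consensus_set: Sequence[TEConsensus],
    min_support: int = 4,
    match_id: float = 0.80,
    match_len: int = 200,
    validation_length: int = 5000,
) -> FilteredInsertionSet:
    """Support / PASS / PRECISE / consensus-match filter chain.

    Keeps INS records with support >= ``min_support`` (the printed criterion
    "more than 3 reads"), PASS filter status, precise breakpoints, and an
    aligned match of length >= ``match_len`` at identity >= ``match_id`` to
    any consensus.  ``tandem_count`` counts non-overlapping same-orientation
    consensus matches inside the inserted sequence (head-to-tail arrays);
    records longer than ``validation_length`` are flagged for validation.
    Every input record is either kept or annotated with exactly its first
    failing reason, in the order: svtype -> support -> filter -> precision
    -> consensus match.
    """
    kept, rejected = [], []
    for call in calls:
        if call.svtype != "INS":
            rejected.append((call, "svtype"))
            continue
        if call.support < min_support:
            rejected.append((call, "support"))
            continue
        if "PASS" not in call.filter_flags:
            rejected.append((call, "filter"))
            continue
        if not call.precise:
            rejected.append((call, "precision"))
            continue
        best_family, best_hits = None, []
        for cons in consensus_set:
            if not call.inserted_seq:
                break
            hits = [
                h for h in local_matches(cons.sequence, call.inserted_seq,
                                         min_id=match_id, min_len=match_len)
                if h["end"] - h["start"] >= match_len
            ]
            if hits:
                span = sum(h["end"] - h["start"] for h in hits)
                if best_family is None or span > sum(h["end"] - h["start"] for h in best_hits):
                    best_family, best_hits = cons.name, hits
        if best_family is None:
            rejected.append((call, "no_consensus_match"))
            continue
        strands = [h["strand"] for h in best_hits]
        major = max(set(strands), key=strands.count)
        tandem = _count_nonoverlapping([h for h in best_hits if h["strand"] == major])
        kept.append(
            KeptInsertion(
                call=call,
                family=best_family,
                tandem_count=tandem,
                needs_validation=call.length > validation_length,
            )
        )
    return FilteredInsertionSet(kept=kept, rejected=rejected)


def _count_nonoverlapping(hits) -> int:
    count, last_end = 0, -1
    for h in sorted(hits, key=lambda h: h["start"]):
        if h["start"] >= last_end:
            count += 1
            last_end = h["end"]
    return count


# ---------------------------------------------------------------------------
# element-level methylation
# ---------------------------------------------------------------------------

@dataclass
class ElementMethylation:
    mean: float
    sd: float
    n_sites: int
    per_copy_means: pd.Series     # copy_id -> mean


def element_methylation(
    calls: pd.DataFrame,
    copies: Sequence[TECopy],
    channel: str = "mc",
) -> ElementMethylation:
    """Pooled (mean, SD) of CpG modification over element copies.

    Sites falling inside each copy locus are pooled; the per-copy means are
    also reported.  At least one copy with one site is required.
    """
    col = {"mc": "mc_frac", "hmc": "hmc_frac"}[channel]
    by_contig = dict(tuple(calls.groupby("contig", observed=True)))
    pooled, per_copy = [], {}
    for c in copies:
        sub = by_contig.get(c.contig)
        if sub is None:
            continue
        pos = sub["pos"].to_numpy()
        lo, hi = np.searchsorted(pos, [c.start, c.end])
        vals = sub[col].to_numpy()[lo:hi]
        if len(vals):
            pooled.append(vals)
            per_copy[c.copy_id] = float(vals.mean())
    if not pooled:
        raise ValueError("no CpG sites within any copy locus")
    allv = np.concatenate(pooled)
    return ElementMethylation(
        mean=float(allv.mean()),
        sd=float(allv.std(ddof=1)) if len(allv) > 1 else float("nan"),
        n_sites=len(allv),
        per_copy_means=pd.Series(per_copy),
    )


def copy_profiles(
    calls: pd.DataFrame,
    copies: Sequence[TECopy],
    channel: str = "mc",
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Per-copy (consensus positions, fractions) for rolling profiles.

    Positions are projected by offset within the matched consensus span
    (strand-aware); indel-free copies project exactly.
    """
    col = {"mc": "mc_frac", "hmc": "hmc_frac"}[channel]
    by_contig = dict(tuple(calls.groupby("contig", observed=True)))
    out = {}
    for c in copies:
        sub = by_contig.get(c.contig)
        if sub is None:
            continue
        pos = sub["pos"].to_numpy()
        lo, hi = np.searchsorted(pos, [c.start, c.end])
        if hi == lo:
            continue
        p = pos[lo:hi]
        if c.strand == "+":
            proj = c.consensus_start + (p - c.start)
        else:
            proj = c.consensus_end - 1 - (p - c.start)
        out[c.copy_id] = (proj.astype(float), sub[col].to_numpy()[lo:hi])
    return out
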