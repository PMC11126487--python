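"""Genome feature tracks and sequence-derived covariates.

Interval algebra (merge, complement, overlap fractions) over typed tracks,
Gardiner-Garden/Frommer-style CpG-island detection, GC and indetermination
content, and CpG-site enumeration.  Coordinates are 0-based half-open
throughout; strand is ignored for all coverage computations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np

from .io import GenomeSequence

FEATURE_CLASSES = (
    "gene", "exon", "intron", "utr5", "utr3", "intergenic",
    "te", "tandem_repeat", "satellite", "cpg_island", "n_block",
)

Interval = tuple[str, int, int, str, str]  # contig, start, end, strand, id


@dataclass
class FeatureTrack:
    """Typed genomic intervals, stored per contig and kept sorted by start."""

    feature_class: str
    by_contig: dict = field(default_factory=dict)

    @classmethod
    def from_intervals(cls, feature_class: str, intervals: Iterable[Interval]):
        track = cls(feature_class)
        for contig, start, end, strand, name in intervals:
            if end < start:
                raise ValueError(f"interval with end < start: {contig}:{start}-{end}")
            track.by_contig.setdefault(contig, []).append((int(start), int(end), strand, name))
        for contig in track.by_contig:
            track.by_contig[contig].sort(key=lambda iv: (iv[0], iv[1]))
        return track

    def iter_intervals(self) -> Iterator[Interval]:
        for contig in sorted(self.by_contig):
            for start, end, strand, name in self.by_contig[contig]:
                yield contig, start, end, strand, name

    def __len__(self) -> int:
        return sum(len(v) for v in self.by_contig.values())

    def total_bases(self) -> int:
        return sum(e - s for _, s, e, _, _ in self.iter_intervals())

    def merge(self) -> "FeatureTrack":
        """Union of the intervals: pairwise-disjoint, sorted, strand dropped."""
        merged = FeatureTrack(self.feature_class)
        for contig, ivs in self.by_contig.items():
            out = []
            for start, end, _, _ in sorted(ivs):
                if out and start <= out[-1][1]:
                    out[-1][1] = max(out[-1][1], end)
                else:
                    out.append([start, end])
            merged.by_contig[contig] = [
                (s, e, ".", f"{self.feature_class}_{contig}_{i}")
                for i, (s, e) in enumerate(out)
            ]
        return merged

    def complement(self, genome: Sequence[GenomeSequence] | Mapping[str, int],
                   feature_class: str = "complement") -> "FeatureTrack":
        """Intervals not covered by this (merged) track, per genome contig.

        Together with ``self.merge()`` the result partitions every contig.
        Intervals of the track on contigs absent from the genome are an error.
        """
        lengths = _contig_lengths(genome)
        unknown = set(self.by_contig) - set(lengths)
        if unknown:
            raise ValueError(f"track has intervals on contigs absent from genome: {sorted(unknown)}")
        merged = self.merge()
        out = FeatureTrack(feature_class)
        for contig, length in lengths.items():
            gaps = []
            cursor = 0
            for start, end, _, _ in merged.by_contig.get(contig, []):
                if start > length or end > length:
                    raise ValueError(f"interval beyond contig end: {contig}:{start}-{end}")
                if start > cursor:
                    gaps.append((cursor, start))
                cursor = max(cursor, end)
            if cursor < length:
                gaps.append((cursor, length))
            out.by_contig[contig] = [
                (s, e, ".", f"{feature_class}_{contig}_{i}") for i, (s, e) in enumerate(gaps)
            ]
        return out

    def overlap_bases(self, contig: str, start: int, end: int) -> int:
        """Total bases of (merged) overlap with window ``[start, end)``."""
        total = 0
        last_end = start
        for s, e, _, _ in self.by_contig.get(contig, []):
            if e <= start:
                continue
            if s >= end:
                break
            lo, hi = max(s, last_end), min(e, end)
            if hi > lo:
                total += hi - lo
                last_end = hi
        return total

    def intersect_fraction(self, window: tuple[str, int, int]) -> float:
        """Fraction of the window covered by the track (merged overlap)."""
        contig, start, end = window
        if end <= start:
            raise ValueError(f"zero-length window {contig}:{start}-{end}")
        return self.overlap_bases(contig, start, end) / (end - start)

    def coverage_mask(self, contig: str, length: int) -> np.ndarray:
        """Boolean per-base membership array for one contig."""
        mask = np.zeros(length, dtype=bool)
        for s, e, _, _ in self.by_contig.get(contig, []):
            mask[s:e] = True
        return mask

    def membership(self, contig: str, positions: np.ndarray) -> np.ndarray:
        """Boolean membership of each (sorted or unsorted) position."""
        ivs = self.by_contig.get(contig, [])
        if not ivs:
            return np.zeros(len(positions), dtype=bool)
        merged = self.merge().by_contig.get(contig, [])
        starts = np.array([s for s, _, _, _ in merged])
        ends = np.array([e for _, e, _, _ in merged])
        idx = np.searchsorted(starts, positions, side="right") - 1
        ok = idx >= 0
        out = np.zeros(len(positions), dtype=bool)
        out[ok] = positions[ok] < ends[idx[ok]]
        return out


def _contig_lengths(genome) -> dict[str, int]:
    if isinstance(genome, Mapping):
        return dict(genome)
    return {g.contig_id: len(g.sequence) for g in genome}


def complement(track: FeatureTrack, genome, feature_class: str = "complement") -> FeatureTrack:
    """Module-level alias of :meth:`FeatureTrack.complement`."""
    return track.complement(genome, feature_class)


def intersect_fraction(track: FeatureTrack, window: tuple[str, int, int]) -> float:
    return track.intersect_fraction(window)


# ---------------------------------------------------------------------------
# sequence-derived annotation
# ---------------------------------------------------------------------------

def _seq_array(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode(), dtype="S1")


def gc_n_content(seq: str, window: tuple[int, int] | None = None) -> tuple[float, float]:
    """(GC fraction over non-N bases, N fraction over all bases).

    An all-N window has undefined GC content and returns ``nan`` for it.
    """
    if window is not None:
        seq = seq[window[0]:window[1]]
    if not seq:
        raise ValueError("empty window")
    arr = _seq_array(seq)
    n = int((arr == b"N").sum())
    n_frac = n / len(arr)
    informative = len(arr) - n
    if informative == 0:
        return float("nan"), n_frac
    gc = int((arr == b"G").sum() + (arr == b"C").sum())
    return gc / informative, n_frac


def enumerate_cpg_sites(genome) -> dict[str, np.ndarray]:
    """All 0-based positions i with ``seq[i:i+2] == "CG"`` per contig."""
    if isinstance(genome, GenomeSequence):
        genome = [genome]
    out = {}
    for g in genome:
        arr = _seq_array(g.sequence)
        hits = np.flatnonzero((arr[:-1] == b"C") & (arr[1:] == b"G"))
        out[g.contig_id] = hits.astype(np.int64)
    return out


def detect_cpg_islands(seq, min_len: int = 200, min_gc: float = 0.5,
                       min_oe: float = 0.6, contig_id: str | None = None) -> FeatureTrack:
    """CpG islands by the length / GC / observed-expected CpG criterion.

    A sliding window of ``min_len`` is scored at every start position; all
    qualifying windows are unioned and maximal runs reported as islands
    (each island therefore has length >= ``min_len``, GC >= ``min_gc`` and
    CpG observed/expected >= ``min_oe`` in every generating window, where
    expected = #C * #G / window length).
    """
    if isinstance(seq, GenomeSequence):
        contig_id = contig_id or seq.contig_id
        seq = seq.sequence
    contig_id = contig_id or "seq"
    track = FeatureTrack("cpg_island")
    L = len(seq)
    if L < min_len:
        track.by_contig[contig_id] = []
        return track
    arr = _seq_array(seq)
    is_c = (arr == b"C").astype(np.int64)
    is_g = (arr == b"G").astype(np.int64)
    is_cg = np.zeros(L, dtype=np.int64)
    is_cg[:-1] = (arr[:-1] == b"C") & (arr[1:] == b"G")

    def wsum(x):
        cs = np.concatenate([[0], np.cumsum(x)])
        return cs[min_len:] - cs[:-min_len]

    c, g, cg = wsum(is_c), wsum(is_g), wsum(is_cg)
    gc_ok = (c + g) / min_len >= min_gc
    expected = c * g / min_len
    with np.errstate(divide="ignore", invalid="ignore"):
        oe = np.where(expected > 0, cg / np.maximum(expected, 1e-300), 0.0)
    ok = gc_ok & (oe >= min_oe)
    # union of all qualifying windows [i, i + min_len)
    starts = np.flatnonzero(ok)
    intervals = []
    for s in starts:
        e = s + min_len
        if intervals and s <= intervals[-1][1]:
            intervals[-1][1] = max(intervals[-1][1], e)
        else:
            intervals.append([int(s), int(e)])
    track.by_contig[contig_id] = [
        (s, e, ".", f"cpg_island_{contig_id}_{i}") for i, (s, e) in enumerate(intervals)
    ]
    return track
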