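"""Readers and writers for the on-disk formats the pipeline touches.

Conventions fixed here and used everywhere else in the package:

* all internal coordinates are 0-based, half-open ``[start, end)``;
* VCF positions (1-based) are shifted on load, BED is taken as-is;
* per-CpG modification calls use a bedMethyl-style TSV dialect with one row
  per site per modification code (``m`` = 5mC, ``h`` = 5hmC) and a fraction
  column in ``[0, 1]``; the two rows of one site are merged into a single
  record on load.  Evidence from both strands is assumed to have been
  collapsed onto the plus-strand C of each CpG before the table was written,
  and the same convention is used by the simulator.
* written tabular files carry a ``# btnmeth=<version>`` comment header
  (``##btnmeth=`` for VCF); FASTA and newick have no comment syntax and are
  written bare.
"""

from __future__ import annotations

import io as _io
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import pysam
from Bio import Phylo, SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import __version__

logger = logging.getLogger(__name__)

_VALID_BASES = frozenset("ACGTN")
_HEADER = f"# btnmeth={__version__}"

METHYL_COLUMNS = ["contig", "pos", "mc_frac", "hmc_frac", "depth", "sample_id"]


@dataclass(frozen=True)
class GenomeSequence:
    """One contig of a genome assembly, uppercase over ``{A,C,G,T,N}``."""

    contig_id: str
    sequence: str

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class CpGSiteCall:
    """Merged 5mC/5hmC call at one CpG site in one sample.

    ``pos`` is the 0-based position of the CpG's C on the plus strand.
    """

    contig: str
    pos: int
    mc_frac: float
    hmc_frac: float
    depth: int
    sample_id: str = ""


@dataclass
class InsertionCall:
    """A sniffles-style structural-variant insertion record."""

    contig: str
    pos: int  # 0-based
    svtype: str
    length: int
    support: int
    filter_flags: frozenset
    precise: bool
    inserted_seq: str = ""
    record_id: str = ""

    def __post_init__(self) -> None:
        if self.length < 0:
            raise ValueError(f"negative SV length for {self.record_id!r}")
        if self.inserted_seq and len(self.inserted_seq) != self.length:
            raise ValueError(
                f"SVLEN {self.length} != len(inserted_seq) "
                f"{len(self.inserted_seq)} for {self.record_id!r}"
            )


@dataclass(frozen=True)
class ExpressionRecord:
    gene_id: str
    raw_count: float
    effective_length: float
    tpm: float = float("nan")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path) -> list[GenomeSequence]:
    """Load a FASTA file as a list of uppercase :class:`GenomeSequence`.

    Duplicate contig ids and letters outside ``{A,C,G,T,N}`` are rejected
    with the offending id / position named in the error.
    """
    seqs: list[GenomeSequence] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate contig id {rec.id!r} in {path}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        if not seq:
            raise ValueError(f"empty sequence for contig {rec.id!r} in {path}")
        bad = re.search(r"[^ACGTN]", seq)
        if bad:
            raise ValueError(
                f"non-IUPAC letter {bad.group()!r} at {rec.id}:{bad.start()} in {path}"
            )
        seqs.append(GenomeSequence(rec.id, seq))
    return seqs


def write_fasta(seqs: Iterable[GenomeSequence], path, width: int = 80):
    records = [
        SeqRecord(Seq(s.sequence), id=s.contig_id, description="") for s in seqs
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)
    return Path(path)


# ---------------------------------------------------------------------------
# per-CpG modification calls (bedMethyl-style dialect)
# ---------------------------------------------------------------------------

_METHYL_FILE_COLS = [
    "contig", "start", "end", "mod_code", "depth", "strand", "frac_modified",
]


def read_methyl_table(path, sample_id: str | None = None) -> pd.DataFrame:
    """Read a per-CpG modification table into the canonical call frame.

    The on-disk dialect has one row per site per modification code; 5mC and
    5hmC rows at the same position are merged.  Depth-0 rows are dropped with
    a warning (their fractions are undefined).  A site with an ``h`` row but
    no ``m`` row is an error naming the line.
    """
    df = pd.read_csv(
        path, sep="\t", comment="#", header=None, names=_METHYL_FILE_COLS,
        dtype={"contig": str, "mod_code": str, "strand": str},
    )
    if ((df["frac_modified"] < 0) | (df["frac_modified"] > 1)).any():
        i = int(df.index[(df["frac_modified"] < 0) | (df["frac_modified"] > 1)][0])
        raise ValueError(f"fraction outside [0,1] at data line {i + 1} of {path}")
    if (df["depth"] < 0).any():
        i = int(df.index[df["depth"] < 0][0])
        raise ValueError(f"negative depth at data line {i + 1} of {path}")
    n_zero = int((df["depth"] == 0).sum())
    if n_zero:
        logger.warning("%s: dropped %d depth-0 rows (fractions undefined)", path, n_zero)
        df = df[df["depth"] > 0]

    m = df[df["mod_code"] == "m"].set_index(["contig", "start"])
    h = df[df["mod_code"] == "h"].set_index(["contig", "start"])
    orphan = h.index.difference(m.index)
    if len(orphan):
        contig, start = orphan[0]
        raise ValueError(
            f"5hmC row without matching 5mC row at {contig}:{start} in {path}"
        )
    out = pd.DataFrame(
        {
            "contig": m.index.get_level_values(0),
            "pos": m.index.get_level_values(1).astype(np.int64),
            "mc_frac": m["frac_modified"].to_numpy(),
            "hmc_frac": h["frac_modified"].reindex(m.index).fillna(0.0).to_numpy(),
            "depth": m["depth"].to_numpy(np.int64),
            "sample_id": sample_id if sample_id is not None else "",
        }
    )
    return out.sort_values(["contig", "pos"], ignore_index=True)


def write_methyl_table(calls: pd.DataFrame, path):
    """Write the canonical call frame back to the two-row-per-site dialect."""
    rows = []
    for mod, col in (("m", "mc_frac"), ("h", "hmc_frac")):
        part = pd.DataFrame(
            {
                "contig": calls["contig"],
                "start": calls["pos"],
                "end": calls["pos"] + 2,
                "mod_code": mod,
                "depth": calls["depth"],
                "strand": "+",
                "frac_modified": calls[col].map(repr),
            }
        )
        rows.append(part)
    table = pd.concat(rows).sort_values(["contig", "start", "mod_code"])
    with open(path, "w") as fh:
        fh.write(_HEADER + "\n")
        table.to_csv(fh, sep="\t", header=False, index=False)
    return Path(path)


def calls_to_records(calls: pd.DataFrame) -> list[CpGSiteCall]:
    return [
        CpGSiteCall(r.contig, int(r.pos), float(r.mc_frac), float(r.hmc_frac),
                    int(r.depth), str(r.sample_id))
        for r in calls.itertuples(index=False)
    ]


def validate_calls(calls: pd.DataFrame, genome: Sequence[GenomeSequence]) -> None:
    """Check every call sits on a CG dinucleotide of the supplied genome."""
    seqs = {g.contig_id: g.sequence for g in genome}
    if (calls["mc_frac"] + calls["hmc_frac"] > 1 + 1e-9).any():
        raise ValueError("mc_frac + hmc_frac > 1 at some site")
    for contig, sub in calls.groupby("contig", observed=True):
        seq = seqs.get(contig)
        if seq is None:
            raise ValueError(f"calls on unknown contig {contig!r}")
        pos = sub["pos"].to_numpy()
        arr = np.frombuffer(seq.encode(), dtype="S1")
        bad = (pos + 1 >= len(seq)) | (arr[pos] != b"C") | (arr[pos + 1] != b"G")
        if bad.any():
            p = int(pos[bad][0])
            raise ValueError(f"call at {contig}:{p} does not sit on a CpG")


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

def read_bed(path, feature_class: str):
    """Read a BED file (>=4 columns used: contig, start, end, name[, score, strand])."""
    from .features import FeatureTrack  # local import to avoid a cycle

    df = pd.read_csv(
        path, sep="\t", comment="#", header=None,
        names=["contig", "start", "end", "name", "score", "strand"],
        usecols=range(6), dtype={"contig": str, "name": str, "strand": str},
    )
    if (df["end"] <= df["start"]).any():
        bad = df[df["end"] <= df["start"]].iloc[0]
        raise ValueError(
            f"BED interval with end <= start at {bad['contig']}:{bad['start']} in {path}"
        )
    intervals = [
        (str(r.contig), int(r.start), int(r.end),
         r.strand if r.strand in ("+", "-") else ".", str(r.name))
        for r in df.itertuples(index=False)
    ]
    return FeatureTrack.from_intervals(feature_class, intervals)


def write_bed(track, path):
    with open(path, "w") as fh:
        fh.write(_HEADER + "\n")
        for contig, start, end, strand, name in track.iter_intervals():
            fh.write(f"{contig}\t{start}\t{end}\t{name}\t0\t{strand}\n")
    return Path(path)


# ---------------------------------------------------------------------------
# VCF (INS records)
# ---------------------------------------------------------------------------

def read_insertion_vcf(path) -> list[InsertionCall]:
    """Load sniffles-style SV records; POS is shifted to 0-based on load.

    Non-INS records are kept but flagged through their ``svtype`` field.
    SUPPORT comes from the INFO key of that name, precision from the PRECISE
    flag, and the FILTER column supplies the filter flags (PASS included).
    """
    calls: list[InsertionCall] = []
    with pysam.VariantFile(str(path)) as vf:
        for rec in vf:
            info = rec.info
            svtype = str(info.get("SVTYPE", "NA"))
            alt = rec.alts[0] if rec.alts else ""
            inserted = ""
            if svtype == "INS" and alt and not alt.startswith("<"):
                inserted = alt[len(rec.ref):]
            length = abs(int(info.get("SVLEN", len(inserted))))
            calls.append(
                InsertionCall(
                    contig=rec.contig,
                    pos=rec.pos - 1,
                    svtype=svtype,
                    length=length,
                    support=int(info.get("SUPPORT", 0)),
                    filter_flags=frozenset(rec.filter.keys()),
                    precise=bool(info.get("PRECISE", False)),
                    inserted_seq=inserted,
                    record_id=rec.id or "",
                )
            )
    return calls


VCF_HEADER = "\n".join(
    [
        "##fileformat=VCFv4.2",
        f"##btnmeth={__version__}",
        '##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">',
        '##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="SV length">',
        '##INFO=<ID=SUPPORT,Number=1,Type=Integer,Description="Supporting reads">',
        '##INFO=<ID=PRECISE,Number=0,Type=Flag,Description="Precise breakpoints">',
        '##INFO=<ID=IMPRECISE,Number=0,Type=Flag,Description="Imprecise breakpoints">',
        '##FILTER=<ID=GT,Description="Genotype filter failed">',
    ]
)


def write_insertion_vcf(calls: Iterable[InsertionCall], contig_lengths: Mapping[str, int], path):
    """Write insertion calls as a plain-text VCF 4.2 file."""
    lines = [VCF_HEADER]
    for contig, length in contig_lengths.items():
        lines.append(f"##contig=<ID={contig},length={length}>")
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO")
    for c in calls:
        alt = "N" + c.inserted_seq if c.inserted_seq else "<INS>"
        info = [f"SVTYPE={c.svtype}", f"SVLEN={c.length}", f"SUPPORT={c.support}"]
        info.append("PRECISE" if c.precise else "IMPRECISE")
        filt = ";".join(sorted(c.filter_flags)) or "."
        lines.append(
            f"{c.contig}\t{c.pos + 1}\t{c.record_id or '.'}\tN\t{alt}\t.\t{filt}\t"
            + ";".join(info)
        )
    Path(path).write_text("\n".join(lines) + "\n")
    return Path(path)


# ---------------------------------------------------------------------------
# newick
# ---------------------------------------------------------------------------

def write_newick(tree, path):
    """Write a Bio.Phylo tree (or a ready newick string) to ``path``."""
    if isinstance(tree, str):
        Path(path).write_text(tree.rstrip() + "\n")
    else:
        Phylo.write(tree, str(path), "newick")
    return Path(path)


def read_newick(path):
    return Phylo.read(str(path), "newick")


# ---------------------------------------------------------------------------
# expression count tables
# ---------------------------------------------------------------------------

def read_expression_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"gene_id", "count", "effective_length"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"expression table {path} missing columns {sorted(missing)}")
    if (df["effective_length"] <= 0).any():
        raise ValueError(f"non-positive effective_length in {path}")
    if (df["count"] < 0).any():
        raise ValueError(f"negative count in {path}")
    return df


def write_expression_table(df: pd.DataFrame, path):
    with open(path, "w") as fh:
        fh.write(_HEADER + "\n")
        df.to_csv(fh, sep="\t", index=False)
    return Path(path)


def write_tsv(df: pd.DataFrame, path):
    """Generic result-table writer with the pipeline version header."""
    with open(path, "w") as fh:
        fh.write(_HEADER + "\n")
        df.to_csv(fh, sep="\t", index=False)
    return Path(path)
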