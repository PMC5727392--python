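"""Readers and writers for the plain-text formats the pipeline touches.

FASTA genomes/regions, BED6 intron coordinates, tab-separated splicing
event tables, and position weight matrices (PWMs).

Coordinate conventions
----------------------
On disk, intervals are BED-style: 0-based, half-open ``[start, end)``.
Inside an intron, offsets are reported as *negative* positions counted
from the 3' end: position ``-1`` is the last intron nucleotide (the G of
the terminal AG), ``-2`` the A, and so on.  This matches the convention
used throughout 3' splice-site analyses ("adenosine -25" style), where
branch points and other elements are located relative to the 3'ss AG.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO

__all__ = [
    "BASES",
    "FormatError",
    "GenomicInterval",
    "IntronRecord",
    "PwmMatrix",
    "EventTable",
    "Region",
    "reverse_complement",
    "read_fasta",
    "write_fasta",
    "read_bed_introns",
    "write_bed_introns",
    "three_prime_region",
    "read_pwm",
    "write_pwm",
    "pwm_from_iupac",
    "sf1_pwm",
    "read_event_table",
    "write_event_table",
]

BASES = "ACGT"

#: IUPAC degeneracy codes over DNA, used both for motif matching and for
#: consensus-derived PWMs.  ``N`` in a *sequence* never matches anything
#: (conservative handling of ambiguous calls); ``N`` in a *pattern* allows
#: the four unambiguous bases.
IUPAC = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "U": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

_RC = str.maketrans("ACGTNacgtn", "TGCANtgcan")


class FormatError(ValueError):
    """A file did not conform to the expected on-disk format."""


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA sequence (N maps to N)."""
    return seq.translate(_RC)[::-1]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenomicInterval:
    """A stranded genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(require 0 <= start < end)"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class IntronRecord:
    """An intron with coordinates and its sense-strand sequence.

    ``sequence`` is always given 5'->3' on the strand of transcription,
    i.e. it ends with the 3' splice-site AG for a canonical intron
    regardless of genomic strand.  Flanking-exon lengths and transcript
    length are optional metadata used by the feature comparisons.
    """

    interval: GenomicInterval
    sequence: str
    name: str = ""
    gene_id: str = ""
    upstream_exon_len: int = 0
    downstream_exon_len: int = 0
    transcript_len: int | None = None

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.interval):
            raise ValueError(
                f"sequence length {len(self.sequence)} != interval length "
                f"{len(self.interval)} for {self.name or self.interval}"
            )
        bad = set(self.sequence.upper()) - set("ACGTN")
        if bad:
            raise ValueError(f"non-ACGTN characters in sequence: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.sequence)


class Region(str):
    """A 3'-end subsequence; behaves as ``str`` but carries a truncation flag.

    ``truncated`` is True when the requested window was longer than the
    intron, in which case the whole intron sequence is returned.
    """

    truncated: bool

    def __new__(cls, seq: str, truncated: bool = False) -> "Region":
        obj = super().__new__(cls, seq)
        obj.truncated = truncated
        return obj


@dataclass(frozen=True)
class PwmMatrix:
    """A position weight matrix over {A, C, G, T}.

    ``probs`` has shape (width, 4) in base order A, C, G, T; every row sums
    to 1.  Scores are log2 odds against ``background``; an N in the scanned
    sequence contributes 0 (scores as background).
    """

    probs: np.ndarray
    pseudocount: float = 0.0
    background: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25)
    )

    def __post_init__(self) -> None:
        probs = np.asarray(self.probs, dtype=float)
        object.__setattr__(self, "probs", probs)
        object.__setattr__(self, "background", np.asarray(self.background, dtype=float))
        if probs.ndim != 2 or probs.shape[1] != 4 or probs.shape[0] < 1:
            raise ValueError("PWM must have shape (width >= 1, 4)")
        if not np.allclose(probs.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("PWM rows must each sum to 1 (after pseudocounts)")

    @property
    def width(self) -> int:
        return self.probs.shape[0]

    @property
    def log_odds(self) -> np.ndarray:
        """(width, 4) matrix of log2(P(base)/background(base)); a true zero
        probability (pseudocount 0) yields -inf, i.e. a forbidden base."""
        with np.errstate(divide="ignore"):
            return np.log2(self.probs / self.background)

    @classmethod
    def from_counts(cls, counts: np.ndarray, pseudocount: float = 0.0,
                    background: np.ndarray | None = None) -> "PwmMatrix":
        counts = np.asarray(counts, dtype=float)
        if counts.ndim != 2 or counts.shape[1] != 4:
            raise ValueError("count matrix must have 4 columns (A C G T)")
        rowsums = counts.sum(axis=1)
        if np.any(rowsums <= 0):
            bad = int(np.flatnonzero(rowsums <= 0)[0]) + 1
            raise FormatError(f"PWM row {bad} does not sum to a positive value")
        probs = (counts + pseudocount) / (rowsums + 4 * pseudocount)[:, None]
        bg = np.full(4, 0.25) if background is None else np.asarray(background, float)
        return cls(probs=probs, pseudocount=pseudocount, background=bg)


def pwm_from_iupac(pattern: str, pseudocount: float = 0.01) -> PwmMatrix:
    """Build a PWM from an IUPAC consensus, equal weight to allowed bases.

    Default stand-in for the SF1 branch-point binding matrix, built from
    the YNYYRAY consensus; a published matrix may be supplied instead via
    :func:`read_pwm`.
    """
    counts = np.zeros((len(pattern), 4))
    for i, code in enumerate(pattern.upper()):
        try:
            allowed = IUPAC[code]
        except KeyError:
            raise ValueError(f"unknown IUPAC code {code!r} in pattern") from None
        for b in allowed:
            counts[i, BASES.index(b)] = 1.0 / len(allowed)
    return PwmMatrix.from_counts(counts, pseudocount=pseudocount)


def sf1_pwm() -> PwmMatrix:
    """Default SF1 branch-point PWM (YNYYRAY consensus, pseudocount 0.01)."""
    return pwm_from_iupac("YNYYRAY", pseudocount=0.01)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a multi-record FASTA into ``{name: sequence}``.

    Names are truncated at the first whitespace; sequences are uppercased
    and U is converted to T.  Duplicate names and empty files are errors.
    """
    records: dict[str, str] = {}
    try:
        for rec in SeqIO.parse(str(path), "fasta"):
            if rec.id in records:
                raise FormatError(f"{path}: duplicate sequence name {rec.id!r}")
            records[rec.id] = str(rec.seq).upper().replace("U", "T")
    except ValueError as exc:  # biopython signals malformed records
        raise FormatError(f"{path}: {exc}") from exc
    if not records:
        raise FormatError(f"{path}: empty or headerless FASTA file")
    return records


def write_fasta(path: str | Path, sequences: Mapping[str, str], width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# BED6 introns
# ---------------------------------------------------------------------------

def read_bed_introns(path: str | Path, fasta: Mapping[str, str]) -> list[IntronRecord]:
    """Read BED6 intron coordinates and extract sense-strand sequences.

    Minus-strand intervals are reverse complemented so that every returned
    :class:`IntronRecord` reads 5'->3' in the direction of transcription.
    """
    introns: list[IntronRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise FormatError(f"{path}:{lineno}: expected 6 BED columns, got {len(fields)}")
            chrom, start_s, end_s, name, _score, strand = fields[:6]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates") from None
            if start >= end:
                raise FormatError(f"{path}:{lineno}: record {name!r} has start >= end")
            if chrom not in fasta:
                raise FormatError(f"{path}:{lineno}: record {name!r}: unknown chrom {chrom!r}")
            chrom_seq = fasta[chrom]
            if end > len(chrom_seq):
                raise FormatError(
                    f"{path}:{lineno}: record {name!r} extends past end of {chrom} "
                    f"({end} > {len(chrom_seq)})"
                )
            seq = chrom_seq[start:end]
            if strand == "-":
                seq = reverse_complement(seq)
            interval = GenomicInterval(chrom, start, end, strand)
            introns.append(IntronRecord(interval=interval, sequence=seq,
                                        name=name, gene_id=name))
    return introns


def write_bed_introns(path: str | Path, introns: Iterable[IntronRecord]) -> None:
    with open(path, "w") as fh:
        for rec in introns:
            iv = rec.interval
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{rec.name or rec.gene_id}\t0\t{iv.strand}\n")


def three_prime_region(intron: IntronRecord | str, n: int) -> Region:
    """The last ``min(n, len)`` nucleotides of the sense-strand intron.

    Position -1 is the last intron nucleotide (the G of the 3' AG), -2 the
    A, etc.  Windows like "positions -104 to -29 from the 3'ss AG" or "the
    3' 150 nucleotides of each intron" are slices of this region.  When the
    intron is shorter than ``n`` the whole intron is returned with
    ``truncated`` set.
    """
    if n < 1:
        raise ValueError("window size must be >= 1")
    seq = intron.sequence if isinstance(intron, IntronRecord) else str(intron)
    if n >= len(seq):
        return Region(seq, truncated=n > len(seq))
    return Region(seq[-n:], truncated=False)


# ---------------------------------------------------------------------------
# PWM files (plain 4-column TSV, rows = positions, columns = A C G T)
# ---------------------------------------------------------------------------

def read_pwm(path: str | Path, pseudocount: float = 0.01) -> PwmMatrix:
    """Read a PWM from a 4-column TSV of counts or probabilities.

    A header row of base letters is allowed.  Rows are normalized with the
    given pseudocount; background is uniform 0.25 per base.
    """
    rows: list[list[float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.replace(",", "\t").split()
            if lineno == 1 and all(f.upper() in set("ACGT") for f in fields):
                continue  # header row of base names
            try:
                values = [float(f) for f in fields]
            except ValueError:
                raise FormatError(f"{path}:{lineno}: non-numeric PWM entry") from None
            if len(values) != 4:
                raise FormatError(f"{path}:{lineno}: expected 4 columns (A C G T), got {len(values)}")
            rows.append(values)
    if not rows:
        raise FormatError(f"{path}: empty PWM file")
    return PwmMatrix.from_counts(np.array(rows), pseudocount=pseudocount)


def write_pwm(path: str | Path, pwm: PwmMatrix) -> None:
    with open(path, "w") as fh:
        fh.write("A\tC\tG\tT\n")
        for row in pwm.probs:
            fh.write("\t".join(format(v, ".6g") for v in row) + "\n")


# ---------------------------------------------------------------------------
# event tables
# ---------------------------------------------------------------------------

#: identifying (non-count) columns of an event table, in on-disk order
META_COLUMNS = ["EVENT_ID", "GENE_ID", "TYPE", "CHROM", "STRAND", "COORDS"]
CE_COUNTS = ["INC1", "INC2", "EXC"]
IR_COUNTS = ["EI1", "EI2", "EE"]


@dataclass
class EventTable:
    """Per-sample junction counts and gene FPKM for a set of splicing events.

    The layout mirrors a VAST-TOOLS-style quantification: one row per
    cassette-exon (CE) or retained-intron (IR) event, and for each sample
    ``s`` the columns ``INC1_s, INC2_s, EXC_s`` (CE inclusion/exclusion
    junction reads) or ``EI1_s, EI2_s, EE_s`` (exon-intron boundary and
    exon-exon junction reads), plus ``FPKM_s`` for the host gene.
    """

    df: pd.DataFrame
    samples: list[str]

    def __post_init__(self) -> None:
        missing = [c for c in META_COLUMNS if c not in self.df.columns]
        if missing:
            raise FormatError(f"event table missing mandatory column(s): {', '.join(missing)}")
        if len(self.samples) != len(set(self.samples)):
            raise FormatError("sample names are not unique")
        ids = self.df["EVENT_ID"]
        if ids.duplicated().any():
            dup = ids[ids.duplicated()].iloc[0]
            raise FormatError(f"duplicate event id {dup!r}")
        bad_type = set(self.df["TYPE"]) - {"CE", "IR"}
        if bad_type:
            raise FormatError(f"unknown event TYPE(s): {sorted(bad_type)}")
        for etype, family in (("CE", CE_COUNTS), ("IR", IR_COUNTS)):
            if (self.df["TYPE"] == etype).any():
                for s in self.samples:
                    for base in family:
                        col = f"{base}_{s}"
                        if col not in self.df.columns:
                            raise FormatError(
                                f"event table has {etype} rows but is missing column {col!r}"
                            )

    def __len__(self) -> int:
        return len(self.df)

    def counts(self, event_id: str, sample: str) -> tuple[int, int, int]:
        """(inc1, inc2, exc) for CE rows, (ei1, ei2, ee) for IR rows."""
        row = self.df.set_index("EVENT_ID").loc[event_id]
        family = CE_COUNTS if row["TYPE"] == "CE" else IR_COUNTS
        return tuple(int(row[f"{b}_{sample}"]) for b in family)

    def fpkm(self, sample: str) -> pd.Series:
        return self.df.set_index("EVENT_ID")[f"FPKM_{sample}"]


def _table_columns(df: pd.DataFrame, samples: list[str]) -> list[str]:
    cols = list(META_COLUMNS)
    has_ce = (df["TYPE"] == "CE").any()
    has_ir = (df["TYPE"] == "IR").any()
    for s in samples:
        if has_ce:
            cols += [f"{b}_{s}" for b in CE_COUNTS]
        if has_ir:
            cols += [f"{b}_{s}" for b in IR_COUNTS]
        cols.append(f"FPKM_{s}")
    return cols


def read_event_table(path: str | Path) -> EventTable:
    """Read a TSV event table; see :class:`EventTable` for the layout."""
    df = pd.read_csv(path, sep="\t", dtype={"EVENT_ID": str, "GENE_ID": str,
                                            "TYPE": str, "CHROM": str,
                                            "STRAND": str, "COORDS": str},
                     na_values=["NA"], keep_default_na=False)
    if df.empty and df.columns.size == 0:
        raise FormatError(f"{path}: empty event table")
    samples = [c[len("FPKM_"):] for c in df.columns if c.startswith("FPKM_")]
    if not samples:
        raise FormatError(f"{path}: no FPKM_<sample> columns found")
    for c in df.columns:
        if any(c.startswith(p + "_") for p in CE_COUNTS + IR_COUNTS):
            df[c] = df[c].astype("Int64")
        elif c.startswith("FPKM_"):
            df[c] = df[c].astype(float)
    return EventTable(df=df, samples=samples)


def write_event_table(path: str | Path, table: EventTable) -> None:
    cols = _table_columns(table.df, table.samples)
    out = table.df.reindex(columns=cols)
    out.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.6g")
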