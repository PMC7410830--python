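"""Readers and writers for the external formats the pipeline touches.

Every genomic coordinate in this package is 0-based, half-open
(``start`` inclusive, ``end`` exclusive), the native BED/bedGraph
convention.  Readers validate coordinates at the boundary so downstream
code can assume well-formed intervals; writers emit standard BED and
bedGraph text that round-trips losslessly through the matching reader.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


class ParseError(ValueError):
    """A malformed line in an external file; the message names the line."""


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open genomic interval, optionally stranded.

    ``name``, ``score`` and ``state`` carry the optional BED columns
    (state is the integer chromatin-state label used by segmentations).
    """

    chrom: str
    start: int
    end: int
    strand: str | None = None
    name: str | None = None
    score: float | None = None
    state: int | None = None

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand is not None and self.strand not in {"+", "-"}:
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass
class TssTable:
    """Transcription start sites, one row per gene.

    ``tss`` is the 0-based position of the start site; ``expressed``
    marks genes that pass the expression filter used for element
    assignment.
    """

    table: pd.DataFrame  # columns: gene_id, chrom, tss, strand, expressed

    REQUIRED = ("gene_id", "chrom", "tss", "strand", "expressed")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ValueError(f"TssTable missing columns: {missing}")
        if self.table["gene_id"].duplicated().any():
            dups = self.table.loc[self.table["gene_id"].duplicated(), "gene_id"]
            raise ValueError(f"duplicate gene ids in TSS table: {sorted(set(dups))[:5]}")
        if (self.table["tss"] < 0).any():
            raise ValueError("TSS positions must be >= 0")

    def expressed_only(self) -> "TssTable":
        return TssTable(self.table[self.table["expressed"]].reset_index(drop=True))

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class SignalTrack:
    """Dense fixed-bin signal over a genome.

    ``values`` maps chromosome name to a per-bin vector; bin ``i``
    covers ``[i*bin_width, (i+1)*bin_width)``.  ``role`` distinguishes
    assay signal from its sequencing-input control.
    """

    values: dict[str, np.ndarray]
    bin_width: int
    sample_id: str = ""
    mark: str = ""
    role: str = "signal"

    def __post_init__(self) -> None:
        if self.bin_width <= 0:
            raise ValueError("bin_width must be positive")
        for chrom, v in self.values.items():
            v = np.asarray(v, dtype=float)
            # raw assay and input tracks are counts-like; derived tracks
            # (log2 ratios) may go negative
            if self.role in {"signal", "input"} and (v < 0).any():
                raise ValueError(f"negative signal values on {chrom}")
            self.values[chrom] = v

    def total_bins(self) -> int:
        return sum(len(v) for v in self.values.values())

    def concatenated(self) -> np.ndarray:
        """All bin values as one vector, chromosomes in sorted order."""
        return np.concatenate([self.values[c] for c in sorted(self.values)])


# ---------------------------------------------------------------------------
# BED

def read_bed(path) -> list[GenomicInterval]:
    """Read a BED3+ file into a list of intervals, preserving input order.

    Column 4 is taken as ``name`` when non-numeric, or as the integer
    ``state`` label when it parses as an integer (segmentation BEDs put
    the state id there).  Column 5 is ``score``, column 6 ``strand``.
    """
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: expected >=3 tab-separated columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinates") from exc
            name = state = score = strand = None
            if len(fields) > 3 and fields[3] != ".":
                try:
                    state = int(fields[3])
                except ValueError:
                    name = fields[3]
            if len(fields) > 4 and fields[4] != ".":
                try:
                    score = float(fields[4])
                except ValueError as exc:
                    raise ParseError(f"{path}:{lineno}: non-numeric score") from exc
            if len(fields) > 5 and fields[5] != ".":
                strand = fields[5]
            try:
                out.append(
                    GenomicInterval(
                        fields[0], start, end,
                        strand=strand, name=name, score=score, state=state,
                    )
                )
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return out


def write_bed(intervals: Iterable[GenomicInterval], path) -> None:
    """Write intervals as BED, emitting only the columns that are set."""
    with open(path, "w") as fh:
        for iv in intervals:
            fields = [iv.chrom, str(iv.start), str(iv.end)]
            col4 = iv.name if iv.name is not None else (
                str(iv.state) if iv.state is not None else None
            )
            extra = [col4, iv.score, iv.strand]
            # trim trailing unset columns, fill interior gaps with '.'
            while extra and extra[-1] is None:
                extra.pop()
            for x in extra:
                if x is None:
                    fields.append(".")
                elif isinstance(x, float):
                    fields.append(format(x, "g"))
                else:
                    fields.append(str(x))
            fh.write("\t".join(fields) + "\n")


# ---------------------------------------------------------------------------
# bedGraph

def read_bedgraph(path, bin_width: int, chrom_sizes: dict[str, int] | None = None,
                  **track_kwargs) -> SignalTrack:
    """Read a bedGraph whose intervals lie on a fixed bin grid.

    Absent bins are zero.  If ``chrom_sizes`` is given, each chromosome
    vector is padded to cover it; otherwise the last seen interval
    defines the extent.
    """
    per_chrom: dict[str, dict[int, float]] = {}
    max_end: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ParseError(f"{path}:{lineno}: expected 4 columns")
            chrom, start, end, value = fields[0], int(fields[1]), int(fields[2]), float(fields[3])
            if start % bin_width or end % bin_width or start >= end:
                raise ParseError(
                    f"{path}:{lineno}: interval {chrom}:{start}-{end} "
                    f"not aligned to {bin_width}-bp bin grid"
                )
            bins = per_chrom.setdefault(chrom, {})
            for b in range(start // bin_width, end // bin_width):
                bins[b] = value
            max_end[chrom] = max(max_end.get(chrom, 0), end)
    values: dict[str, np.ndarray] = {}
    for chrom, bins in per_chrom.items():
        extent = max_end[chrom]
        if chrom_sizes is not None:
            extent = max(extent, chrom_sizes[chrom])
        n = -(-extent // bin_width)
        v = np.zeros(n)
        for b, x in bins.items():
            v[b] = x
        values[chrom] = v
    if chrom_sizes is not None:
        for chrom, size in chrom_sizes.items():
            values.setdefault(chrom, np.zeros(-(-size // bin_width)))
    return SignalTrack(values=values, bin_width=bin_width, **track_kwargs)


def write_bedgraph(track: SignalTrack, path) -> None:
    """Write a track as bedGraph, merging runs of equal value and
    omitting zero runs (the reader restores them)."""
    bw = track.bin_width
    with open(path, "w") as fh:
        for chrom in sorted(track.values):
            v = track.values[chrom]
            i = 0
            while i < len(v):
                j = i
                while j < len(v) and v[j] == v[i]:
                    j += 1
                if v[i] != 0.0:
                    fh.write(f"{chrom}\t{i * bw}\t{j * bw}\t{format(v[i], 'g')}\n")
                i = j


# ---------------------------------------------------------------------------
# Expression / cell matrices (TSV, genes or cells in rows)

def read_matrix(path, index_name: str = "gene_id") -> pd.DataFrame:
    """Read a TSV matrix with row ids in the first column.

    Raises on duplicate row or column ids.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index.name = index_name
    if df.index.duplicated().any():
        raise ValueError(f"duplicate row ids in {path}")
    if df.columns.duplicated().any():
        raise ValueError(f"duplicate column ids in {path}")
    return df


def write_matrix(df: pd.DataFrame, path, float_format: str = "%.6g") -> None:
    df.to_csv(path, sep="\t", float_format=float_format)


def read_tss_table(path) -> TssTable:
    df = pd.read_csv(path, sep="\t")
    if "expressed" in df.columns:
        df["expressed"] = df["expressed"].astype(bool)
    return TssTable(df)


def write_tss_table(tss: TssTable, path) -> None:
    tss.table.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path) -> dict[str, str]:
    """Read a genome FASTA into {chrom: uppercase sequence}."""
    genome: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in genome:
            raise ValueError(f"duplicate sequence id {rec.id!r} in {path}")
        genome[rec.id] = str(rec.seq).upper()
    return genome


def write_fasta(genome: dict[str, str], path, width: int = 80) -> None:
    records = [
        SeqRecord(Seq(seq), id=chrom, description="") for chrom, seq in genome.items()
    ]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# MEME motifs

@dataclass
class PWM:
    """A position probability matrix (4 x L, rows A, C, G, T)."""

    motif_id: str
    matrix: np.ndarray  # shape (4, L), columns sum to 1
    source: str = ""

    ALPHABET = "ACGT"

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[0] != 4:
            raise ValueError("PWM matrix must be 4 x L")
        sums = self.matrix.sum(axis=0)
        if np.any(np.abs(sums - 1.0) > 1e-6):
            raise ValueError(f"PWM {self.motif_id}: columns do not sum to 1")

    @property
    def length(self) -> int:
        return self.matrix.shape[1]

    def consensus(self) -> str:
        return "".join(self.ALPHABET[i] for i in self.matrix.argmax(axis=0))


# Tolerance for renormalizing published matrices whose columns are off by
# rounding; anything worse is treated as a corrupt file.
PWM_RENORM_TOL = 1e-3


def read_meme_motifs(path) -> list[PWM]:
    """Parse a MEME (minimal) motif file into a list of PWMs.

    Columns whose probabilities sum to within ``PWM_RENORM_TOL`` of 1
    are renormalized; larger deviations raise.
    """
    motifs: list[PWM] = []
    with open(path) as fh:
        lines = fh.readlines()
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        if line.startswith("MOTIF"):
            parts = line.split()
            motif_id = parts[1]
            # find the letter-probability header
            j = i + 1
            while j < len(lines) and not lines[j].strip().startswith(
                "letter-probability"
            ):
                if lines[j].strip().startswith("MOTIF"):
                    raise ParseError(f"{path}: motif {motif_id} has no matrix")
                j += 1
            if j >= len(lines):
                raise ParseError(f"{path}: motif {motif_id} has no matrix")
            header = lines[j].strip()
            w = None
            for tok_i, tok in enumerate(parts_ := header.replace("=", " = ").split()):
                if tok == "w" and tok_i + 2 < len(parts_):
                    w = int(parts_[tok_i + 2])
            rows = []
            j += 1
            while j < len(lines):
                s = lines[j].strip()
                if not s or s.startswith(("MOTIF", "URL")):
                    break
                rows.append([float(x) for x in s.split()])
                j += 1
            mat = np.array(rows, dtype=float).T  # -> 4 x L
            if mat.shape[0] != 4:
                raise ParseError(f"{path}: motif {motif_id} rows must have 4 values")
            if w is not None and mat.shape[1] != w:
                raise ParseError(
                    f"{path}: motif {motif_id} declares w={w} but has {mat.shape[1]} rows"
                )
            sums = mat.sum(axis=0)
            bad = np.abs(sums - 1.0) > PWM_RENORM_TOL
            if bad.any():
                raise ParseError(
                    f"{path}: motif {motif_id} column sums deviate from 1 "
                    f"beyond {PWM_RENORM_TOL} (worst {sums[bad][0]:.4f})"
                )
            mat = mat / sums
            motifs.append(PWM(motif_id=motif_id, matrix=mat))
            i = j
        else:
            i += 1
    return motifs


def write_meme_motifs(motifs: Sequence[PWM], path) -> None:
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        fh.write(
            "Background letter frequencies\nA 0.25 C 0.25 G 0.25 T 0.25\n\n"
        )
        for m in motifs:
            fh.write(f"MOTIF {m.motif_id}\n")
            fh.write(
                f"letter-probability matrix: alength= 4 w= {m.length} "
                f"nsites= 20 E= 0\n"
            )
            for col in m.matrix.T:
                fh.write(" ".join(f"{x:.6f}" for x in col) + "\n")
            fh.write("\n")
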