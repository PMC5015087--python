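"""Coordinate data model and readers/writers for the text formats the pipeline touches.

All interval arithmetic is 0-based half-open (BED convention). BED is the
canonical interchange format for intervals and fragment positions, bedGraph
the canonical track format. Expression arrives as a pre-computed per-gene
table (the role of a Cufflinks output); this module never fits expression
models.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, TextIO

import numpy as np
import pandas as pd

__all__ = [
    "Genome",
    "Interval",
    "Fragment",
    "CoverageTrack",
    "GeneAnnotation",
    "parse_chrom_sizes",
    "read_bed",
    "write_bed",
    "read_fragments",
    "write_fragments",
    "coverage_from_fragments",
    "write_bedgraph",
    "read_bedgraph",
    "read_expression_table",
    "write_expression_table",
    "filter_expressed",
    "read_gene_table",
    "write_gene_table",
    "read_gmt",
    "write_gmt",
]

EXPRESSION_COLUMNS = ["gene_id", "fpkm_a", "fpkm_b", "log2fc", "stat", "fdr"]
GENE_COLUMNS = ["gene_id", "chrom", "strand", "tx_start", "tx_end", "cds_start", "cds_end"]


class ParseError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass(frozen=True)
class Genome:
    """Ordered registry of chromosome name -> length (bp).

    Iteration order is the input order; it is the coordinate authority for
    every downstream interval and track.
    """

    chromosomes: dict[str, int]

    def __post_init__(self) -> None:
        for name, length in self.chromosomes.items():
            if not isinstance(length, (int, np.integer)) or length <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length {length!r}")

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.chromosomes

    def __iter__(self) -> Iterator[str]:
        return iter(self.chromosomes)

    def length(self, chrom: str) -> int:
        try:
            return self.chromosomes[chrom]
        except KeyError:
            raise KeyError(f"unknown chromosome {chrom!r}") from None

    @property
    def total_length(self) -> int:
        return sum(self.chromosomes.values())

    def n_bins(self, chrom: str, bin_size: int) -> int:
        return -(-self.length(chrom) // bin_size)


@dataclass(frozen=True, order=True)
class Interval:
    """A genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    name: str = "."
    score: float = 0.0
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} (need 0 <= start < end)"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "Interval") -> bool:
        return self.chrom == other.chrom and self.start < other.end and other.start < self.end


@dataclass(frozen=True)
class Fragment:
    """A sequenced fragment anchored at its 5' end.

    ``five_prime`` is the 5'-most base of the read: ``start`` for + strand,
    ``end - 1`` for - strand. Extension to the modelled fragment length
    proceeds from this anchor in the strand direction.
    """

    chrom: str
    five_prime: int
    strand: str
    length: int

    def extended_span(self, extend_to: int, chrom_length: int) -> tuple[int, int]:
        """Half-open span after extension to ``extend_to`` bp, clipped."""
        if self.strand == "+":
            lo, hi = self.five_prime, self.five_prime + extend_to
        else:
            lo, hi = self.five_prime - extend_to + 1, self.five_prime + 1
        return max(0, lo), min(chrom_length, hi)

    def midpoint(self, fragment_size: int, chrom_length: int) -> int:
        """5' end shifted by fragment_size // 2 in the strand direction, clipped."""
        shift = fragment_size // 2
        mid = self.five_prime + shift if self.strand == "+" else self.five_prime - shift
        return min(max(mid, 0), chrom_length - 1)


@dataclass
class CoverageTrack:
    """Binned signal per chromosome.

    ``values[chrom]`` has length ceil(L / bin_size). Raw tracks hold the
    number of extended fragments overlapping each bin (per-base coverage at
    bin_size 1); normalized tracks are scaled by library size and may be
    negative (subtraction tracks).
    """

    genome: Genome
    bin_size: int
    values: dict[str, np.ndarray]
    total_fragments: int = 0
    normalized: bool = False
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")
        for chrom in self.genome:
            n = self.genome.n_bins(chrom, self.bin_size)
            if chrom not in self.values:
                self.values[chrom] = np.zeros(n)
            elif len(self.values[chrom]) != n:
                raise ValueError(
                    f"{chrom}: expected {n} bins, got {len(self.values[chrom])}"
                )

    def same_grid(self, other: "CoverageTrack") -> bool:
        return (
            self.bin_size == other.bin_size
            and self.genome.chromosomes == other.genome.chromosomes
        )

    def normalize(self, scale: float = 1e6) -> "CoverageTrack":
        """Fragments-per-million track (values / total_fragments * scale)."""
        if self.total_fragments <= 0:
            raise ValueError("cannot normalize a track with no fragments")
        vals = {c: v * (scale / self.total_fragments) for c, v in self.values.items()}
        return CoverageTrack(
            self.genome, self.bin_size, vals, self.total_fragments, normalized=True,
            metadata=dict(self.metadata),
        )

    def region_sum(self, chrom: str, start: int, end: int) -> float:
        """Sum of per-base signal over [start, end).

        Bin values are treated as uniform per-base levels within the bin,
        exact at bin_size 1, so partial bins contribute pro rata.
        """
        v = self.values[chrom]
        b = self.bin_size
        lo, hi = max(0, start), min(self.genome.length(chrom), end)
        if hi <= lo:
            return 0.0
        first, last = lo // b, (hi - 1) // b
        if first == last:
            return float(v[first] * (hi - lo))
        total = v[first] * ((first + 1) * b - lo) + v[last] * (hi - last * b)
        if last - first > 1:
            total += v[first + 1 : last].sum() * b
        return float(total)

    def region_density(self, chrom: str, start: int, end: int) -> float:
        """Mean per-base signal over [start, end)."""
        return self.region_sum(chrom, start, end) / max(1, end - start)


@dataclass(frozen=True)
class GeneAnnotation:
    """A gene record with strand-aware TSS.

    The TSS is tx_start for + strand genes and tx_end for - strand genes
    (the coordinate the transcript starts from, in BED convention).
    """

    gene_id: str
    chrom: str
    strand: str
    tx_start: int
    tx_end: int
    cds_start: int = 0
    cds_end: int = 0

    def __post_init__(self) -> None:
        if self.tx_start >= self.tx_end:
            raise ValueError(f"{self.gene_id}: tx_start must be < tx_end")
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be + or -")
        if self.cds_start != self.cds_end:
            if not (self.tx_start <= self.cds_start < self.cds_end <= self.tx_end):
                raise ValueError(f"{self.gene_id}: CDS not nested in transcript")

    @property
    def tss(self) -> int:
        return self.tx_start if self.strand == "+" else self.tx_end


# ---------------------------------------------------------------------------
# chrom.sizes


def parse_chrom_sizes(stream: TextIO | str) -> Genome:
    """Parse two-column name/length text into a Genome (input order kept)."""
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    chroms: dict[str, int] = {}
    for lineno, line in enumerate(stream, 1):
        line = line.strip()
        if not line:
            continue
        fields = line.split()
        if len(fields) < 2:
            raise ParseError(f"line {lineno}: expected two columns, got {line!r}")
        name = fields[0]
        try:
            length = int(fields[1])
        except ValueError:
            raise ParseError(f"line {lineno}: non-integer length {fields[1]!r}") from None
        if length <= 0:
            raise ParseError(f"line {lineno}: non-positive length for {name}")
        if name in chroms:
            raise ParseError(f"line {lineno}: duplicate chromosome {name}")
        chroms[name] = length
    return Genome(chroms)


# ---------------------------------------------------------------------------
# BED


def _bed_lines(stream: TextIO | str) -> Iterator[tuple[int, list[str]]]:
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    for lineno, line in enumerate(stream, 1):
        line = line.rstrip("\n")
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        yield lineno, line.split("\t")


def read_bed(stream: TextIO | str, genome: Genome) -> list[Interval]:
    """Read BED3/BED6 intervals, validating against the genome."""
    out: list[Interval] = []
    for lineno, f in _bed_lines(stream):
        if len(f) < 3:
            raise ParseError(f"line {lineno}: fewer than 3 BED columns")
        chrom = f[0]
        if chrom not in genome:
            raise ParseError(f"line {lineno}: unknown chromosome {chrom!r}")
        try:
            start, end = int(f[1]), int(f[2])
        except ValueError:
            raise ParseError(f"line {lineno}: non-integer coordinates") from None
        if not (0 <= start < end <= genome.length(chrom)):
            raise ParseError(
                f"line {lineno}: invalid interval {chrom}:{start}-{end}"
            )
        name = f[3] if len(f) > 3 else "."
        score = float(f[4]) if len(f) > 4 else 0.0
        strand = f[5] if len(f) > 5 else "."
        out.append(Interval(chrom, start, end, name, score, strand))
    return out


def write_bed(intervals: Iterable[Interval], stream: TextIO) -> None:
    """Write BED6 lines; round-trips bit-exactly through read_bed."""
    for iv in intervals:
        score = repr(iv.score) if iv.score != int(iv.score) else str(int(iv.score))
        stream.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name}\t{score}\t{iv.strand}\n")


def read_fragments(
    stream: TextIO | str, genome: Genome, read_length_default: int = 36
) -> list[Fragment]:
    """Read aligned-read positions from BED6; strand is mandatory.

    The 5' end is the BED start for + reads and end-1 for - reads.
    """
    frags: list[Fragment] = []
    for lineno, f in _bed_lines(stream):
        if len(f) < 6:
            raise ParseError(f"line {lineno}: fragments need 6 BED columns (strand)")
        chrom = f[0]
        if chrom not in genome:
            raise ParseError(f"line {lineno}: unknown chromosome {chrom!r}")
        start, end = int(f[1]), int(f[2])
        if not (0 <= start < end <= genome.length(chrom)):
            raise ParseError(f"line {lineno}: out-of-bounds read {chrom}:{start}-{end}")
        strand = f[5]
        if strand not in ("+", "-"):
            raise ParseError(f"line {lineno}: missing or invalid strand {strand!r}")
        length = end - start if end > start else read_length_default
        five_prime = start if strand == "+" else end - 1
        frags.append(Fragment(chrom, five_prime, strand, length))
    return frags


def write_fragments(fragments: Iterable[Fragment], stream: TextIO) -> None:
    """Write fragments as BED6 read positions (inverse of read_fragments)."""
    for i, fr in enumerate(fragments):
        if fr.strand == "+":
            start, end = fr.five_prime, fr.five_prime + fr.length
        else:
            start, end = fr.five_prime - fr.length + 1, fr.five_prime + 1
        stream.write(f"{fr.chrom}\t{start}\t{end}\tr{i}\t0\t{fr.strand}\n")


# ---------------------------------------------------------------------------
# coverage


def fragment_arrays(
    fragments: Iterable[Fragment], genome: Genome
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Group fragments by chromosome into (five_prime, is_forward) arrays."""
    five: dict[str, list[int]] = {c: [] for c in genome}
    fwd: dict[str, list[bool]] = {c: [] for c in genome}
    for fr in fragments:
        five[fr.chrom].append(fr.five_prime)
        fwd[fr.chrom].append(fr.strand == "+")
    return {
        c: (np.asarray(five[c], dtype=np.int64), np.asarray(fwd[c], dtype=bool))
        for c in genome
    }


def coverage_from_fragments(
    fragments: Iterable[Fragment],
    genome: Genome,
    bin_size: int = 1,
    extend_to: int = 260,
) -> CoverageTrack:
    """Accumulate extended-fragment coverage into a binned raw track.

    Each fragment is extended from its 5' end in the strand direction to
    ``extend_to`` bp (clipped at chromosome bounds) and contributes +1 to
    every bin it overlaps.
    """
    arrays = fragment_arrays(fragments, genome)
    values: dict[str, np.ndarray] = {}
    n = 0
    for chrom, (five, fwd) in arrays.items():
        L = genome.length(chrom)
        nb = genome.n_bins(chrom, bin_size)
        lo = np.where(fwd, five, five - extend_to + 1).clip(0, L)
        hi = np.where(fwd, five + extend_to, five + 1).clip(0, L)
        keep = hi > lo
        lo, hi = lo[keep], hi[keep]
        n += len(lo)
        b0 = lo // bin_size
        b1 = (hi - 1) // bin_size
        diff = np.bincount(b0, minlength=nb + 1) - np.bincount(b1 + 1, minlength=nb + 2)[: nb + 1]
        values[chrom] = np.cumsum(diff[:nb]).astype(float)
    return CoverageTrack(genome, bin_size, values, total_fragments=n, normalized=False)


# ---------------------------------------------------------------------------
# bedGraph


def write_bedgraph(track: CoverageTrack, stream: TextIO) -> None:
    """Emit runs of equal value as bedGraph lines; zero runs are omitted."""
    b = track.bin_size
    for chrom in track.genome:
        v = track.values[chrom]
        L = track.genome.length(chrom)
        if len(v) == 0:
            continue
        change = np.flatnonzero(np.diff(v)) + 1
        starts = np.concatenate(([0], change))
        ends = np.concatenate((change, [len(v)]))
        for s, e in zip(starts, ends):
            val = v[s]
            if val == 0:
                continue
            val_s = repr(float(val)) if val != int(val) else str(int(val))
            stream.write(f"{chrom}\t{s * b}\t{min(e * b, L)}\t{val_s}\n")


def read_bedgraph(
    stream: TextIO | str, genome: Genome, bin_size: int = 1
) -> CoverageTrack:
    """Read a bedGraph whose line boundaries align to the bin grid."""
    values = {c: np.zeros(genome.n_bins(c, bin_size)) for c in genome}
    seen = {c: np.zeros(genome.n_bins(c, bin_size), dtype=bool) for c in genome}
    for lineno, f in _bed_lines(stream):
        if len(f) < 4:
            raise ParseError(f"line {lineno}: bedGraph needs 4 columns")
        chrom = f[0]
        if chrom not in genome:
            raise ParseError(f"line {lineno}: unknown chromosome {chrom!r}")
        start, end, val = int(f[1]), int(f[2]), float(f[3])
        L = genome.length(chrom)
        if not (0 <= start < end <= L):
            raise ParseError(f"line {lineno}: span {start}-{end} outside {chrom}")
        if start % bin_size or (end % bin_size and end != L):
            raise ParseError(
                f"line {lineno}: span {start}-{end} not aligned to bin size {bin_size}"
            )
        b0, b1 = start // bin_size, -(-end // bin_size)
        if seen[chrom][b0:b1].any():
            raise ParseError(f"line {lineno}: overlapping bedGraph intervals on {chrom}")
        seen[chrom][b0:b1] = True
        values[chrom][b0:b1] = val
    return CoverageTrack(genome, bin_size, values, normalized=True)


# ---------------------------------------------------------------------------
# expression tables


def read_expression_table(stream: TextIO | str) -> pd.DataFrame:
    """Read the per-gene expression table (TSV with header).

    Required columns: gene_id, fpkm_a, fpkm_b, log2fc, stat, fdr.
    """
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    df = pd.read_csv(stream, sep="\t")
    for col in EXPRESSION_COLUMNS:
        if col not in df.columns:
            raise ParseError(f"expression table missing column {col!r}")
    if df["gene_id"].duplicated().any():
        dup = df["gene_id"][df["gene_id"].duplicated()].iloc[0]
        raise ParseError(f"duplicate gene_id {dup!r} in expression table")
    if (df["fpkm_a"] < 0).any() or (df["fpkm_b"] < 0).any():
        raise ParseError("negative FPKM in expression table")
    if ((df["fdr"] < 0) | (df["fdr"] > 1)).any():
        raise ParseError("fdr outside [0, 1] in expression table")
    return df.reset_index(drop=True)


def write_expression_table(table: pd.DataFrame, stream: TextIO) -> None:
    table[EXPRESSION_COLUMNS].to_csv(stream, sep="\t", index=False)


def filter_expressed(table: pd.DataFrame, min_fpkm: float = 0.05) -> pd.DataFrame:
    """Drop genes with FPKM below ``min_fpkm`` in both conditions."""
    keep = (table["fpkm_a"] >= min_fpkm) | (table["fpkm_b"] >= min_fpkm)
    return table[keep].reset_index(drop=True)


# ---------------------------------------------------------------------------
# gene annotation table


def read_gene_table(stream: TextIO | str, genome: Genome | None = None) -> list[GeneAnnotation]:
    """Read the tab-delimited gene annotation (header: gene_id chrom strand tx_start tx_end cds_start cds_end)."""
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    df = pd.read_csv(stream, sep="\t")
    for col in GENE_COLUMNS:
        if col not in df.columns:
            raise ParseError(f"gene table missing column {col!r}")
    genes = []
    for row in df.itertuples(index=False):
        if genome is not None and row.chrom not in genome:
            raise ParseError(f"gene {row.gene_id}: unknown chromosome {row.chrom!r}")
        genes.append(
            GeneAnnotation(
                str(row.gene_id), row.chrom, row.strand,
                int(row.tx_start), int(row.tx_end), int(row.cds_start), int(row.cds_end),
            )
        )
    return genes


def write_gene_table(genes: Iterable[GeneAnnotation], stream: TextIO) -> None:
    stream.write("\t".join(GENE_COLUMNS) + "\n")
    for g in genes:
        stream.write(
            f"{g.gene_id}\t{g.chrom}\t{g.strand}\t{g.tx_start}\t{g.tx_end}\t{g.cds_start}\t{g.cds_end}\n"
        )


# ---------------------------------------------------------------------------
# GMT gene sets


def read_gmt(stream: TextIO | str) -> dict[str, list[str]]:
    """Read a GMT gene-set file: name, description, members, tab-delimited."""
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    sets: dict[str, list[str]] = {}
    for lineno, line in enumerate(stream, 1):
        line = line.rstrip("\n")
        if not line.strip():
            continue
        f = line.split("\t")
        if len(f) < 3:
            raise ParseError(f"line {lineno}: GMT needs name, description, >=1 member")
        name = f[0]
        if name in sets:
            raise ParseError(f"line {lineno}: duplicate gene set {name!r}")
        members = [g for g in f[2:] if g]
        sets[name] = list(dict.fromkeys(members))
    return sets


def write_gmt(sets: dict[str, list[str]], stream: TextIO) -> None:
    for name, members in sets.items():
        stream.write("\t".join([name, "na", *members]) + "\n")
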