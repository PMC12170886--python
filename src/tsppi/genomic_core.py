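"""Genomic interval primitives and plain-text format IO.

All coordinates are 0-based half-open (BED convention) internally; GFF3
input (1-based closed) is converted on read.  Everything downstream —
consensus peak building, annotation, promoter derivation, motif sequence
extraction — goes through the types defined here.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

FEATURE_LABELS = frozenset(
    {"exon", "intron", "promoter", "utr3", "utr5", "enhancer", "cpg_island", "tfbs", "ctcf"}
)


class ValidationError(ValueError):
    """Raised when a record violates a data-model invariant."""


class ParseError(ValueError):
    """Raised on malformed input; message names the offending line."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open genomic interval [start, end) with optional strand."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    name: str = ""
    score: float = 0.0

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValidationError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} (need 0 <= start < end)"
            )
        if self.strand not in ("+", "-", "."):
            raise ValidationError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start


def midpoint(interval: GenomicInterval) -> int:
    """Midpoint base of an interval; even lengths floor to the lower base."""
    return (interval.start + interval.end - 1) // 2


def overlap_fraction(a: GenomicInterval, b: GenomicInterval) -> float:
    """Fraction of ``a`` covered by ``b`` (asymmetric)."""
    if a.chrom != b.chrom:
        return 0.0
    inter = min(a.end, b.end) - max(a.start, b.start)
    return max(inter, 0) / len(a)


@dataclass(frozen=True)
class GeneModel:
    """A gene with strand-aware TSS and optional exon structure."""

    gene_id: str
    name: str
    interval: GenomicInterval
    exons: tuple[GenomicInterval, ...] = ()
    biotype: str = "protein_coding"

    def __post_init__(self) -> None:
        for ex in self.exons:
            if ex.chrom != self.interval.chrom or ex.start < self.interval.start or ex.end > self.interval.end:
                raise ValidationError(f"exon {ex} outside gene {self.gene_id} span")
        srt = sorted(self.exons, key=lambda e: e.start)
        for prev, nxt in zip(srt, srt[1:]):
            if nxt.start < prev.end:
                raise ValidationError(f"overlapping exons in gene {self.gene_id}")

    @property
    def strand(self) -> str:
        return self.interval.strand

    @property
    def tss(self) -> int:
        """Transcription start site: interval start on '+', last base on '-'."""
        return self.interval.start if self.strand != "-" else self.interval.end - 1

    def introns(self) -> list[GenomicInterval]:
        srt = sorted(self.exons, key=lambda e: e.start)
        out = []
        for prev, nxt in zip(srt, srt[1:]):
            if nxt.start > prev.end:
                out.append(GenomicInterval(self.interval.chrom, prev.end, nxt.start, self.strand))
        return out


def promoter_of(
    gene: GeneModel, width_bp: int = 2000, chrom_length: int | None = None
) -> GenomicInterval | None:
    """2-kb (default) region upstream of the TSS of a protein-coding gene.

    Returns None for non-protein-coding genes (skip, not error) and for
    promoters fully clipped away at a chromosome edge.
    """
    if gene.biotype != "protein_coding":
        return None
    tss = gene.tss
    if gene.strand == "-":
        start, end = tss + 1, tss + 1 + width_bp
    else:
        start, end = tss - width_bp, tss
    start = max(start, 0)
    if chrom_length is not None:
        end = min(end, chrom_length)
    if start >= end:
        return None
    return GenomicInterval(gene.interval.chrom, start, end, gene.strand)


@dataclass
class FeatureTrack:
    """Labelled set of intervals (enhancers, CpG islands, ...) kept sorted."""

    label: str
    intervals: list[GenomicInterval] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.label not in FEATURE_LABELS:
            raise ValidationError(f"unknown feature label {self.label!r}")
        self.intervals = sorted(self.intervals, key=lambda iv: (iv.chrom, iv.start))


class CoverageTrack:
    """Per-chromosome run-length encoded coverage (depth >= 0).

    Runs are stored as parallel numpy arrays (starts, ends, depths), sorted
    and non-overlapping; uncovered bases are implicitly depth 0.
    """

    def __init__(self, runs: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] | None = None):
        self._runs: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = runs or {}

    @classmethod
    def from_records(cls, records: Iterable[tuple[str, int, int, float]]) -> "CoverageTrack":
        by_chrom: dict[str, list[tuple[int, int, float]]] = {}
        for chrom, start, end, depth in records:
            if start >= end:
                raise ValidationError(f"bad run {chrom}:{start}-{end}")
            if not np.isfinite(depth) or depth < 0:
                raise ValidationError(f"depth must be finite and >= 0, got {depth}")
            by_chrom.setdefault(chrom, []).append((start, end, float(depth)))
        runs = {}
        for chrom, lst in by_chrom.items():
            lst.sort()
            for (s1, e1, _), (s2, _, _) in zip(lst, lst[1:]):
                if s2 < e1:
                    raise ValidationError(f"overlapping coverage runs on {chrom} at {s2}")
            starts = np.array([r[0] for r in lst], dtype=np.int64)
            ends = np.array([r[1] for r in lst], dtype=np.int64)
            depths = np.array([r[2] for r in lst], dtype=np.float64)
            runs[chrom] = (starts, ends, depths)
        return cls(runs)

    @property
    def chroms(self) -> list[str]:
        return sorted(self._runs)

    def runs(self, chrom: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return self._runs.get(
            chrom,
            (np.empty(0, np.int64), np.empty(0, np.int64), np.empty(0, np.float64)),
        )

    def total_mass(self) -> float:
        """Sum of depth x length over all runs (conserved by IO round-trips)."""
        return float(
            sum(((e - s) * d).sum() for s, e, d in self._runs.values())
        )

    def sum_over(self, chrom: str, start: int, end: int) -> float:
        """Summed per-base depth over [start, end)."""
        starts, ends, depths = self.runs(chrom)
        if len(starts) == 0:
            return 0.0
        lo = bisect.bisect_right(ends, start)  # first run ending after start
        hi = bisect.bisect_left(starts, end)  # first run starting at/after end
        if lo >= hi:
            return 0.0
        s = np.maximum(starts[lo:hi], start)
        e = np.minimum(ends[lo:hi], end)
        return float(((e - s) * depths[lo:hi]).sum())

    def binned_means(self, chrom: str, start: int, end: int, n_bins: int) -> np.ndarray:
        """Mean depth in n_bins equal bins across [start, end); out-of-range padded 0."""
        width = (end - start) // n_bins
        out = np.zeros(n_bins)
        for i in range(n_bins):
            b0, b1 = start + i * width, start + (i + 1) * width
            if b1 <= 0:
                continue
            c0, c1 = max(b0, 0), b1
            if c0 >= c1:
                continue
            out[i] = self.sum_over(chrom, c0, c1) / width
        return out


@dataclass
class Genome:
    """In-memory genome: chromosome name -> uppercase sequence over ACGTN."""

    sequences: dict[str, str]

    def length(self, chrom: str) -> int:
        return len(self.sequences[chrom])

    @property
    def chroms(self) -> list[str]:
        return sorted(self.sequences)

    def fetch(self, interval: GenomicInterval) -> str:
        seq = self.sequences[interval.chrom]
        if interval.end > len(seq):
            raise ValidationError(
                f"interval {interval.chrom}:{interval.start}-{interval.end} exceeds "
                f"chromosome length {len(seq)}"
            )
        sub = seq[interval.start : interval.end]
        if interval.strand == "-":
            sub = str(Seq(sub).reverse_complement())
        return sub


# ---------------------------------------------------------------------------
# Readers / writers


def read_bed(path: str | Path) -> list[GenomicInterval]:
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: expected >=3 tab-separated columns")
            try:
                chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from None
            name = fields[3] if len(fields) > 3 else ""
            try:
                score = float(fields[4]) if len(fields) > 4 and fields[4] != "." else 0.0
            except ValueError:
                raise ParseError(f"{path}:{lineno}: bad score {fields[4]!r}") from None
            strand = fields[5] if len(fields) > 5 else "."
            try:
                out.append(GenomicInterval(chrom, start, end, strand, name, score))
            except ValidationError as exc:
                raise ValidationError(f"{path}:{lineno}: {exc}") from None
    return out


def write_bed(intervals: Sequence[GenomicInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name or '.'}\t{iv.score:g}\t{iv.strand}\n")


def read_bedgraph(path: str | Path) -> CoverageTrack:
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ParseError(f"{path}:{lineno}: expected 4 columns")
            try:
                records.append((fields[0], int(fields[1]), int(fields[2]), float(fields[3])))
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from None
    return CoverageTrack.from_records(records)


def write_bedgraph(track: CoverageTrack, path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom in track.chroms:
            starts, ends, depths = track.runs(chrom)
            for s, e, d in zip(starts, ends, depths):
                fh.write(f"{chrom}\t{s}\t{e}\t{d:g}\n")


def read_fasta(path: str | Path) -> Genome:
    return Genome({rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")})


def write_fasta(genome: Genome, path: str | Path) -> None:
    records = [SeqRecord(Seq(genome.sequences[c]), id=c, description="") for c in genome.chroms]
    SeqIO.write(records, str(path), "fasta")


_GENE_TSV_COLS = ["gene_id", "name", "chrom", "start", "end", "strand", "biotype"]


def read_gene_models(path: str | Path, format: str = "tsv") -> list[GeneModel]:
    """Read gene models from a TSV gene table or a GFF3 subset.

    TSV columns: gene_id, name, chrom, start, end, strand, biotype
    (0-based half-open).  GFF3: gene and exon features, ID/Parent
    attributes, 1-based closed coordinates converted on read.
    """
    if format == "tsv":
        return _read_gene_tsv(path)
    if format == "gff3-subset":
        return _read_gff3(path)
    raise ValueError(f"unknown gene model format {format!r}")


def _read_gene_tsv(path: str | Path) -> list[GeneModel]:
    out = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {c: header.index(c) for c in _GENE_TSV_COLS}
        for lineno, line in enumerate(fh, 2):
            if not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            try:
                iv = GenomicInterval(f[idx["chrom"]], int(f[idx["start"]]), int(f[idx["end"]]), f[idx["strand"]])
            except (ValueError, ValidationError) as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from None
            out.append(GeneModel(f[idx["gene_id"]], f[idx["name"]], iv, (), f[idx["biotype"]]))
    return out


def write_gene_tsv(genes: Sequence[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_GENE_TSV_COLS) + "\n")
        for g in genes:
            fh.write(
                f"{g.gene_id}\t{g.name}\t{g.interval.chrom}\t{g.interval.start}\t"
                f"{g.interval.end}\t{g.strand}\t{g.biotype}\n"
            )


def _parse_gff_attrs(text: str) -> dict[str, str]:
    out = {}
    for part in text.strip().split(";"):
        if "=" in part:
            k, v = part.split("=", 1)
            out[k.strip()] = v.strip()
    return out


def _read_gff3(path: str | Path) -> list[GeneModel]:
    genes: dict[str, dict] = {}
    exons: dict[str, list[GenomicInterval]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 9:
                raise ParseError(f"{path}:{lineno}: expected 9 GFF3 columns")
            chrom, _, ftype, start1, end1, _, strand, _, attrs_text = f[:9]
            attrs = _parse_gff_attrs(attrs_text)
            start, end = int(start1) - 1, int(end1)  # 1-based closed -> half-open
            if ftype == "gene":
                gid = attrs.get("ID", "")
                genes[gid] = dict(
                    gene_id=gid,
                    name=attrs.get("Name", gid),
                    interval=GenomicInterval(chrom, start, end, strand),
                    biotype=attrs.get("biotype", "protein_coding"),
                )
            elif ftype == "exon":
                parent = attrs.get("Parent", "")
                exons.setdefault(parent, []).append(GenomicInterval(chrom, start, end, strand))
    out = []
    for gid, kw in genes.items():
        try:
            out.append(GeneModel(exons=tuple(sorted(exons.get(gid, []), key=lambda e: e.start)), **kw))
        except ValidationError as exc:
            raise ValidationError(f"{path}: gene {gid}: {exc}") from None
    return out
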