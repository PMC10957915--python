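"""Genomic interval algebra, BED/GTF I/O and feature annotation.

All coordinates are 0-based, half-open ``[start, end)`` — BED semantics.
This module is the substrate for every other stage: consensus peak
construction across replicates, promoter windows, feature-class
annotation of peaks, and nearest-gene assignment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

logger = logging.getLogger(__name__)

CONSENSUS_WIDTH = 500
PROMOTER_UP = 2000
PROMOTER_DOWN = 500

FEATURE_CLASSES = ("promoter", "exonic", "intronic", "intergenic")


class BedFormatError(ValueError):
    """Raised for malformed BED-family input, naming the offending line."""

    def __init__(self, path, lineno: int, message: str):
        self.path = str(path)
        self.lineno = lineno
        super().__init__(f"{path}:{lineno}: {message}")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open interval on a named chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self):
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(require 0 <= start < end)"
            )

    @property
    def width(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def overlap_bp(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def contains_point(self, chrom: str, pos: int) -> bool:
        return self.chrom == chrom and self.start <= pos < self.end

    @property
    def name(self) -> str:
        """Coordinate-derived identifier, e.g. ``chr1:250-750``."""
        return f"{self.chrom}:{self.start}-{self.end}"


@dataclass(frozen=True)
class GeneModel:
    """A gene with strand-aware TSS and exon structure."""

    gene_id: str
    interval: GenomicInterval
    strand: str
    exons: tuple = ()

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        for exon in self.exons:
            if not (
                exon.chrom == self.interval.chrom
                and exon.start >= self.interval.start
                and exon.end <= self.interval.end
            ):
                raise ValueError(f"exon {exon} outside gene body of {self.gene_id}")

    @property
    def tss(self) -> int:
        """Transcription start: interval start on '+', end−1 on '-'."""
        if self.strand == "+":
            return self.interval.start
        return self.interval.end - 1

    @property
    def chrom(self) -> str:
        return self.interval.chrom


@dataclass(frozen=True)
class Peak:
    """A signal-bearing peak from one replicate/sample."""

    interval: GenomicInterval
    signal: float = 0.0
    sample_id: str = ""
    name: str = ""

    def __post_init__(self):
        if self.signal < 0:
            raise ValueError(f"peak signal must be >= 0, got {self.signal}")


@dataclass(frozen=True)
class ConsensusPeak:
    """A 500 bp replicate-consensus peak with support count."""

    interval: GenomicInterval
    support: int
    feature_class: str | None = None

    def __post_init__(self):
        if self.interval.width != CONSENSUS_WIDTH:
            raise ValueError(
                f"consensus peak width must be {CONSENSUS_WIDTH}, "
                f"got {self.interval.width}"
            )
        if self.support < 1:
            raise ValueError("support must be >= 1")


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_bed(path, sample_id: str | None = None) -> list[Peak]:
    """Read a BED3/BED4/BED5 file into sorted :class:`Peak` records.

    Column 4 (if present) is the peak name and column 5 the signal.
    Malformed lines raise :class:`BedFormatError` naming the line number.
    """
    path = Path(path)
    if sample_id is None:
        sample_id = path.stem
    peaks: list[Peak] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise BedFormatError(path, lineno, "expected >= 3 tab-separated columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise BedFormatError(path, lineno, "non-integer coordinates") from None
            if start >= end:
                raise BedFormatError(path, lineno, f"start >= end ({start} >= {end})")
            name = fields[3] if len(fields) >= 4 else ""
            signal = 0.0
            if len(fields) >= 5:
                try:
                    signal = float(fields[4])
                except ValueError:
                    raise BedFormatError(path, lineno, "non-numeric signal column") from None
            peaks.append(
                Peak(GenomicInterval(chrom, start, end), signal, sample_id, name)
            )
    peaks.sort(key=lambda p: (p.interval.chrom, p.interval.start, p.interval.end))
    return peaks


def write_bed(path, rows: Iterable[Sequence]) -> None:
    """Write tab-separated rows (first three columns BED coordinates)."""
    with open(path, "w") as fh:
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")


def read_gtf(path) -> list[GeneModel]:
    """Read gene models (``gene`` + ``exon`` features) from a GTF file.

    Uses an in-memory gffutils database; only the ``gene_id`` attribute is
    consulted. GTF 1-based inclusive coordinates are converted to 0-based
    half-open.
    """
    import gffutils

    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    exons_by_gene: dict[str, list[GenomicInterval]] = {}
    for exon in db.features_of_type("exon"):
        gid = exon.attributes["gene_id"][0]
        exons_by_gene.setdefault(gid, []).append(
            GenomicInterval(exon.seqid, exon.start - 1, exon.end)
        )
    genes = []
    for gene in db.features_of_type("gene"):
        gid = gene.attributes["gene_id"][0]
        genes.append(
            GeneModel(
                gene_id=gid,
                interval=GenomicInterval(gene.seqid, gene.start - 1, gene.end),
                strand=gene.strand,
                exons=tuple(sorted(exons_by_gene.get(gid, []))),
            )
        )
    genes.sort(key=lambda g: (g.interval.chrom, g.interval.start, g.gene_id))
    return genes


# ---------------------------------------------------------------------------
# Interval algebra
# ---------------------------------------------------------------------------

def merge_intervals(
    intervals: Iterable[GenomicInterval], gap: int = 0
) -> list[GenomicInterval]:
    """Union-merge intervals; two intervals merge when the edge-to-edge gap
    between them is <= ``gap`` (0 merges overlapping or book-ended)."""
    by_pos = sorted(intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))
    merged: list[GenomicInterval] = []
    for iv in by_pos:
        if merged and iv.chrom == merged[-1].chrom and iv.start - merged[-1].end <= gap:
            last = merged[-1]
            if iv.end > last.end:
                merged[-1] = GenomicInterval(last.chrom, last.start, iv.end)
        else:
            merged.append(iv)
    return merged


def overlap_fraction(
    target: GenomicInterval, others: Iterable[GenomicInterval]
) -> float:
    """Fraction of ``target`` covered by the union of ``others``.

    Union-based, so overlapping members of ``others`` are not double
    counted. Intervals on other chromosomes are ignored.
    """
    clipped = []
    for iv in others:
        if iv.chrom != target.chrom:
            continue
        s, e = max(iv.start, target.start), min(iv.end, target.end)
        if s < e:
            clipped.append(GenomicInterval(target.chrom, s, e))
    if not clipped:
        return 0.0
    covered = sum(iv.width for iv in merge_intervals(clipped))
    return covered / target.width


def consensus_peaks(
    replicate_peaksets: Sequence[Sequence[Peak]], min_support: int = 2
) -> list[ConsensusPeak]:
    """Merge peaks across replicates into 500 bp consensus peaks.

    Overlapping (or book-ended) peaks from any replicates are union-merged;
    merged regions supported by >= ``min_support`` distinct replicates are
    kept, each resized to 500 bp centred on the merged-region midpoint
    (``floor((start+end)/2)``).
    """
    if not replicate_peaksets:
        raise ValueError("need at least one replicate peak set")
    if min_support < 1:
        raise ValueError("min_support must be >= 1")
    if min_support > len(replicate_peaksets):
        # unsatisfiable support filter: nothing can pass
        logger.warning(
            "min_support=%d exceeds the %d replicates supplied; "
            "no consensus peak can satisfy it",
            min_support,
            len(replicate_peaksets),
        )
        return []
    tagged = []
    for rep_idx, peaks in enumerate(replicate_peaksets):
        for p in peaks:
            tagged.append((p.interval.chrom, p.interval.start, p.interval.end, rep_idx))
    tagged.sort()
    out: list[ConsensusPeak] = []
    cur: list | None = None  # [chrom, start, end, set(reps)]
    def _flush(region):
        chrom, start, end, reps = region
        if len(reps) >= min_support:
            mid = (start + end) // 2
            s = max(0, mid - CONSENSUS_WIDTH // 2)
            out.append(
                ConsensusPeak(
                    GenomicInterval(chrom, s, s + CONSENSUS_WIDTH), len(reps)
                )
            )

    for chrom, start, end, rep in tagged:
        if cur is not None and chrom == cur[0] and start <= cur[2]:
            cur[2] = max(cur[2], end)
            cur[3].add(rep)
        else:
            if cur is not None:
                _flush(cur)
            cur = [chrom, start, end, {rep}]
    if cur is not None:
        _flush(cur)
    out.sort(key=lambda cp: (cp.interval.chrom, cp.interval.start))
    return out


# ---------------------------------------------------------------------------
# Gene-centric annotation
# ---------------------------------------------------------------------------

def promoter_window(
    gene: GeneModel, up: int = PROMOTER_UP, down: int = PROMOTER_DOWN
) -> GenomicInterval:
    """Strand-aware promoter window around the TSS (``up`` bp upstream,
    ``down`` bp downstream), clipped at coordinate 0."""
    if gene.strand == "+":
        start, end = gene.tss - up, gene.tss + down
    else:
        start, end = gene.tss - down + 1, gene.tss + up + 1
    return GenomicInterval(gene.chrom, max(0, start), end)


def annotate_feature_class(
    peak: GenomicInterval,
    genes: Sequence[GeneModel],
    promoter_up: int = PROMOTER_UP,
    promoter_down: int = PROMOTER_DOWN,
) -> str:
    """Classify a peak by its midpoint with priority
    promoter > exonic > intronic > intergenic."""
    chrom, mid = peak.chrom, peak.midpoint
    is_exonic = False
    is_intronic = False
    for gene in genes:
        if gene.chrom != chrom:
            continue
        if promoter_window(gene, promoter_up, promoter_down).contains_point(chrom, mid):
            return "promoter"
        if gene.interval.contains_point(chrom, mid):
            if any(ex.contains_point(chrom, mid) for ex in gene.exons):
                is_exonic = True
            else:
                is_intronic = True
    if is_exonic:
        return "exonic"
    if is_intronic:
        return "intronic"
    return "intergenic"


def nearest_genes(
    peak: GenomicInterval, genes: Sequence[GeneModel], n: int = 5
) -> list[str]:
    """The ``n`` genes on the peak's chromosome whose TSS is closest to the
    peak midpoint; ties broken lexicographically by gene_id."""
    if n < 1:
        raise ValueError("n must be >= 1")
    mid = peak.midpoint
    candidates = [
        (abs(g.tss - mid), g.gene_id) for g in genes if g.chrom == peak.chrom
    ]
    candidates.sort()
    return [gid for _, gid in candidates[:n]]
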