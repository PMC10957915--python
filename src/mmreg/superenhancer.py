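"""ROSE-style super-enhancer calling and cross-sample consensus.

Peaks near transcription start sites are excluded, the remainder are
stitched when closer than a stitching distance (defaults: 2500 bp TSS
exclusion, 12 500 bp stitching), stitched regions are ranked by summed
signal, and the classic tangent cutoff on the signal-rank curve splits
super-enhancers (SE) from typical enhancers (TE): with signals sorted
ascending y_1..y_n and chord slope s = (y_n − y_1)/(n − 1), the cutoff
is the signal at the point lying furthest below the chord, and regions
with signal strictly above it are super. Per-sample SEs are then
union-merged into consensus SEs; a sample is a member of a consensus SE
when at least half of its original SE length lies inside it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .intervals import (
    ConsensusPeak,
    GeneModel,
    GenomicInterval,
    Peak,
    merge_intervals,
)

logger = logging.getLogger(__name__)

STITCH_DISTANCE = 12_500
TSS_EXCLUSION = 2_500


@dataclass(frozen=True)
class StitchParams:
    stitch_distance: int = STITCH_DISTANCE
    tss_exclusion: int = TSS_EXCLUSION

    def __post_init__(self):
        if self.stitch_distance < 0 or self.tss_exclusion < 0:
            raise ValueError("stitch parameters must be >= 0")


@dataclass
class StitchedRegion:
    """A stitched enhancer region with its constituent peaks."""

    interval: GenomicInterval
    constituent_peaks: tuple[Peak, ...]
    signal: float
    rank: int | None = None
    is_super: bool = False


@dataclass
class ConsensusSE:
    """A consensus super-enhancer across samples."""

    interval: GenomicInterval
    member_samples: frozenset
    constituent_consensus_peaks: tuple[ConsensusPeak, ...] = ()

    def __post_init__(self):
        if not self.member_samples:
            raise ValueError("consensus SE must have at least one member sample")


def exclude_tss_peaks(
    peaks: Sequence[Peak],
    genes: Sequence[GeneModel],
    tss_exclusion: int = TSS_EXCLUSION,
) -> list[Peak]:
    """Drop peaks overlapping any ``[tss − d, tss + d)`` window."""
    windows = [
        GenomicInterval(g.chrom, max(0, g.tss - tss_exclusion), g.tss + tss_exclusion)
        for g in genes
    ]
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for w in windows:
        by_chrom.setdefault(w.chrom, []).append(w)
    kept = []
    for p in peaks:
        ws = by_chrom.get(p.interval.chrom, ())
        if not any(p.interval.overlaps(w) for w in ws):
            kept.append(p)
    return kept


def stitch(peaks: Sequence[Peak], stitch_distance: int = STITCH_DISTANCE) -> list[StitchedRegion]:
    """Transitively merge peaks whose edge-to-edge gap is <= the stitching
    distance; region signal is the plain sum of constituent signals."""
    ordered = sorted(peaks, key=lambda p: (p.interval.chrom, p.interval.start, p.interval.end))
    regions: list[StitchedRegion] = []
    cluster: list[Peak] = []

    def _flush():
        if not cluster:
            return
        chrom = cluster[0].interval.chrom
        start = min(p.interval.start for p in cluster)
        end = max(p.interval.end for p in cluster)
        regions.append(
            StitchedRegion(
                GenomicInterval(chrom, start, end),
                tuple(cluster),
                float(sum(p.signal for p in cluster)),
            )
        )

    cur_end = None
    for p in ordered:
        if (
            cluster
            and p.interval.chrom == cluster[0].interval.chrom
            and p.interval.start - cur_end <= stitch_distance
        ):
            cluster.append(p)
            cur_end = max(cur_end, p.interval.end)
        else:
            _flush()
            cluster = [p]
            cur_end = p.interval.end
    _flush()
    return regions


def tangent_cutoff(regions: Sequence[StitchedRegion]) -> list[StitchedRegion]:
    """Flag super-enhancers by the signal-rank tangent cutoff.

    Signals sorted ascending y_1..y_n against x_i = i define a chord of
    slope s = (y_n − y_1)/(n − 1); the tangent index t minimises
    y_i − s·i (the point furthest below the chord; ties take the largest
    i) and regions with signal strictly greater than y_t are super.
    Ranks are assigned by descending signal, ties broken by leftmost
    coordinate. Invariant under positive affine rescaling of signals.
    """
    n = len(regions)
    if n < 3:
        raise ValueError("tangent cutoff needs at least 3 stitched regions")
    ys = np.sort(np.asarray([r.signal for r in regions], dtype=float))
    if ys[0] == ys[-1]:
        logger.warning("all stitched-region signals identical; no super-enhancers called")
        cutoff = np.inf
    else:
        # signed distance below the chord, scaled by (n-1) to avoid the
        # slope division: endpoint ties are then exact in floating point,
        # so concave/linear curves resolve to the last index (no supers)
        span = ys[-1] - ys[0]
        d = (ys - ys[0]) * (n - 1) - span * np.arange(n)
        t = n - 1 - int(np.argmin(d[::-1]))  # largest index on ties
        cutoff = ys[t]
    for r in regions:
        r.is_super = bool(r.signal > cutoff)
    order = sorted(
        range(n),
        key=lambda i: (-regions[i].signal, regions[i].interval.chrom, regions[i].interval.start),
    )
    for rank, i in enumerate(order, start=1):
        regions[i].rank = rank
    return list(regions)


def call_superenhancers(
    peaks: Sequence[Peak],
    genes: Sequence[GeneModel],
    params: StitchParams | None = None,
) -> list[StitchedRegion]:
    """Sample-wise SE calling: TSS exclusion, stitching, tangent cutoff."""
    params = params or StitchParams()
    kept = exclude_tss_peaks(peaks, genes, params.tss_exclusion)
    regions = stitch(kept, params.stitch_distance)
    return tangent_cutoff(regions)


def se_membership(original: GenomicInterval, consensus: GenomicInterval) -> bool:
    """Membership rule for re-assigning samples to consensus SEs: at least
    half of the ORIGINAL sample SE length must lie within the consensus."""
    return original.overlap_bp(consensus) / original.width >= 0.5


def consensus_se(
    per_sample_ses: Mapping[str, Sequence[StitchedRegion | GenomicInterval]],
) -> list[ConsensusSE]:
    """Union-merge per-sample SEs into consensus SEs and re-assign samples
    via :func:`se_membership`."""
    if not per_sample_ses:
        raise ValueError("need at least one sample")

    def _iv(x) -> GenomicInterval:
        return x.interval if isinstance(x, StitchedRegion) else x

    all_ivs = [_iv(r) for regions in per_sample_ses.values() for r in regions]
    if not all_ivs:
        return []
    merged = merge_intervals(all_ivs)
    out = []
    for consensus in merged:
        members = set()
        for sample, regions in per_sample_ses.items():
            if any(se_membership(_iv(r), consensus) for r in regions):
                members.add(sample)
        if members:
            out.append(ConsensusSE(consensus, frozenset(members)))
    return out


def assign_constituents(
    consensus_ses: Sequence[ConsensusSE],
    consensus_peaks: Sequence[ConsensusPeak],
) -> list[ConsensusSE]:
    """Attach consensus peaks to every consensus SE containing their
    midpoint; peaks outside all SEs remain typical enhancers."""
    for se in consensus_ses:
        se.constituent_consensus_peaks = tuple(
            cp
            for cp in consensus_peaks
            if se.interval.contains_point(cp.interval.chrom, cp.interval.midpoint)
        )
    return list(consensus_ses)
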