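"""STABILO: enhancer-origin classification from chromatin-state trajectories.

Each locus is scored active/inactive in three developmental groups —
B cells (B), normal plasma cells (PC) and myeloma (MM) — from chromHMM
segmentations, and the activity trajectory is mapped to one of five
origin classes:

===========  ==============================================
de_novo      inactive in B and PC, active only in MM
reactivated  active in B, silent in PC, active again in MM
preserved    active in PC and MM (B-cell status free)
lost         active in B and/or PC but not in MM
unknown      never active
===========  ==============================================

A locus is active in a sample when >= ``min_fraction`` (default 50%,
inclusive) of the locus is covered by the union of segments carrying an
active-enhancer state. A group is active when any of its samples is
(∃ rule). ``de_novo`` and ``reactivated`` together form the "dormant"
enhancer set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .intervals import GenomicInterval, overlap_fraction

logger = logging.getLogger(__name__)

CLASSES = ("de_novo", "reactivated", "preserved", "lost", "unknown")
DORMANT_CLASSES = frozenset({"de_novo", "reactivated"})
GROUPS = ("B", "PC", "MM")


@dataclass(frozen=True)
class StateConfig:
    """Which segmentation state labels count as active enhancers."""

    active_states: frozenset = frozenset({"E9", "E10"})
    min_fraction: float = 0.5

    def __post_init__(self):
        if not self.active_states:
            raise ValueError("active_states must be non-empty")
        if not (0 < self.min_fraction <= 1):
            raise ValueError("min_fraction must be in (0, 1]")


@dataclass(frozen=True)
class StageActivity:
    locus: GenomicInterval
    b_active: bool
    pc_active: bool
    mm_active: bool


class Segmentation:
    """One sample's ordered, non-overlapping state-labelled intervals."""

    def __init__(self, segments: Iterable[tuple[GenomicInterval, str]], sample_id: str = ""):
        self.sample_id = sample_id
        self._by_chrom: dict[str, list[tuple[int, int, str]]] = {}
        for iv, state in segments:
            self._by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end, state))
        for chrom, segs in self._by_chrom.items():
            segs.sort()
            for (s1, e1, _), (s2, _, _) in zip(segs, segs[1:]):
                if s2 < e1:
                    raise ValueError(
                        f"overlapping segments on {chrom} in sample {sample_id!r}"
                    )

    def active_segments(
        self, chrom: str, start: int, end: int, active_states: frozenset
    ) -> list[GenomicInterval]:
        """Segments with an active state overlapping [start, end)."""
        import bisect

        segs = self._by_chrom.get(chrom)
        if segs is None:
            return []
        lo = bisect.bisect_left(segs, (start,)) if segs else 0
        # step back: the previous segment may span `start`
        if lo > 0 and segs[lo - 1][1] > start:
            lo -= 1
        out = []
        for s, e, state in segs[lo:]:
            if s >= end:
                break
            if state in active_states and e > start:
                out.append(GenomicInterval(chrom, s, e))
        return out

    @property
    def chroms(self):
        return set(self._by_chrom)


def _normalize_state(label: str) -> str:
    """Strip chromHMM dense-BED description suffixes, e.g. ``E9_EnhA`` -> ``E9``."""
    return label.split("_", 1)[0]


def read_segmentation(path, sample_id: str | None = None) -> Segmentation:
    """Read a BED4 chromHMM segmentation (column 4 = state label)."""
    path = Path(path)
    if sample_id is None:
        sample_id = path.stem
    segments = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ValueError(f"{path}:{lineno}: segmentation needs 4 columns")
            chrom, start, end, state = fields[0], int(fields[1]), int(fields[2]), fields[3]
            segments.append((GenomicInterval(chrom, start, end), _normalize_state(state)))
    return Segmentation(segments, sample_id)


def read_manifest(path) -> dict[str, str]:
    """Read a two-column TSV mapping sample id -> group (B/PC/MM)."""
    mapping: dict[str, str] = {}
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            sample, group = line.split("\t")[:2]
            if group not in GROUPS:
                raise ValueError(f"unknown group {group!r} for sample {sample!r}")
            mapping[sample] = group
    return mapping


def locus_active_in_sample(
    locus: GenomicInterval, segmentation: Segmentation, cfg: StateConfig
) -> bool:
    """True iff active-state segments cover >= min_fraction of the locus."""
    if locus.chrom not in segmentation.chroms:
        logger.debug(
            "chrom %s absent from segmentation %s; treating locus as inactive",
            locus.chrom,
            segmentation.sample_id,
        )
        return False
    active = segmentation.active_segments(
        locus.chrom, locus.start, locus.end, cfg.active_states
    )
    return overlap_fraction(locus, active) >= cfg.min_fraction


def group_activity(
    locus: GenomicInterval,
    samples_by_group: Mapping[str, Sequence[Segmentation]],
    cfg: StateConfig,
) -> StageActivity:
    """Summarise per-sample activity to the three groups (any-sample rule)."""
    if not samples_by_group.get("MM"):
        raise ValueError("MM group must contain at least one sample")

    def _any(group: str) -> bool:
        return any(
            locus_active_in_sample(locus, seg, cfg)
            for seg in samples_by_group.get(group, ())
        )

    return StageActivity(locus, _any("B"), _any("PC"), _any("MM"))


def classify(activity: StageActivity) -> str:
    """Map a (B, PC, MM) activity triple to its origin class."""
    if activity.mm_active:
        if activity.pc_active:
            return "preserved"
        if activity.b_active:
            return "reactivated"
        return "de_novo"
    if activity.b_active or activity.pc_active:
        return "lost"
    return "unknown"


def is_dormant(stabilo_class: str) -> bool:
    return stabilo_class in DORMANT_CLASSES


def classify_loci(
    loci: Mapping[str, GenomicInterval] | Sequence[GenomicInterval],
    samples_by_group: Mapping[str, Sequence[Segmentation]],
    cfg: StateConfig | None = None,
) -> pd.DataFrame:
    """Classify many loci; returns a frame indexed by locus id.

    ``loci`` may be a mapping id -> interval, or a sequence of intervals
    (ids derived from coordinates).
    """
    cfg = cfg or StateConfig()
    if not isinstance(loci, Mapping):
        loci = {iv.name: iv for iv in loci}
    rows = []
    for locus_id, iv in loci.items():
        act = group_activity(iv, samples_by_group, cfg)
        cls = classify(act)
        rows.append(
            {
                "locus_id": locus_id,
                "chrom": iv.chrom,
                "start": iv.start,
                "end": iv.end,
                "b_active": act.b_active,
                "pc_active": act.pc_active,
                "mm_active": act.mm_active,
                "stabilo_class": cls,
                "dormant": is_dormant(cls),
            }
        )
    return pd.DataFrame(rows).set_index("locus_id")
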