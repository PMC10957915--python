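"""HiChIP loop annotation, EE/EP/PP classification and EPI master table.

Differential loops arrive as BEDPE with 2500 bp anchors; each anchor is
annotated with every overlapping enhancer (differential H3K27ac
consensus peak) and promoter, ambiguous anchors are expanded with an
inclusive all-pairs strategy, and the enhancer–promoter pairs are joined
with enhancer/gene differential statistics, p52 occupancy,
super-enhancer membership, enhancer-origin (STABILO) class, patient
enrichment and essentiality flags into one master table — one row per
(loop, enhancer, gene) triple.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from .intervals import GenomicInterval
from .superenhancer import ConsensusSE

logger = logging.getLogger(__name__)

ANCHOR_WIDTH = 2_500
MIN_LOOP_DISTANCE = 10_000  # exclusive lower bound
MAX_LOOP_DISTANCE = 2_000_000  # inclusive upper bound
FDR_THRESHOLD = 0.1

MASTER_COLUMNS = [
    "loop_id",
    "enhancer_id",
    "gene_id",
    "loop_log2fc",
    "loop_fdr",
    "enhancer_log2fc",
    "enhancer_fdr",
    "gene_log2fc",
    "gene_fdr",
    "p52_bound",
    "se_member",
    "stabilo_class",
    "nfkb_enriched_epigenome",
    "nfkb_enriched_expression",
    "essential",
]


@dataclass(frozen=True)
class Loop:
    """One cis chromatin loop with differential-contact statistics."""

    loop_id: str
    anchor1: GenomicInterval
    anchor2: GenomicInterval
    contact_a: int
    contact_b: int
    log2fc: float
    fdr: float

    def __post_init__(self):
        for a in (self.anchor1, self.anchor2):
            if a.width != ANCHOR_WIDTH:
                raise ValueError(f"anchor width must be {ANCHOR_WIDTH}, got {a.width}")
        if self.anchor1.chrom != self.anchor2.chrom:
            raise ValueError("loops must be cis (same chromosome)")
        if not (MIN_LOOP_DISTANCE < self.distance <= MAX_LOOP_DISTANCE):
            raise ValueError(
                f"loop distance {self.distance} outside "
                f"({MIN_LOOP_DISTANCE}, {MAX_LOOP_DISTANCE}]"
            )
        if not (0 <= self.fdr <= 1):
            raise ValueError("fdr must be in [0, 1]")
        if self.contact_a < 0 or self.contact_b < 0:
            raise ValueError("contact counts must be >= 0")

    @property
    def distance(self) -> int:
        return abs(self.anchor2.midpoint - self.anchor1.midpoint)


@dataclass(frozen=True)
class DiffRecord:
    feature_id: str
    log2fc: float
    pvalue: float
    fdr: float


def read_bedpe(path) -> list[Loop]:
    """Read loops from an 11-column BEDPE:
    chrom1 start1 end1 chrom2 start2 end2 name contact_a contact_b log2fc fdr.
    """
    loops = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 11:
                raise ValueError(f"{path}:{lineno}: expected 11 BEDPE columns")
            loops.append(
                Loop(
                    loop_id=f[6],
                    anchor1=GenomicInterval(f[0], int(f[1]), int(f[2])),
                    anchor2=GenomicInterval(f[3], int(f[4]), int(f[5])),
                    contact_a=int(f[7]),
                    contact_b=int(f[8]),
                    log2fc=float(f[9]),
                    fdr=float(f[10]),
                )
            )
    return loops


def write_bedpe(loops: Sequence[Loop], path) -> None:
    with open(path, "w") as fh:
        for lp in loops:
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        lp.anchor1.chrom,
                        lp.anchor1.start,
                        lp.anchor1.end,
                        lp.anchor2.chrom,
                        lp.anchor2.start,
                        lp.anchor2.end,
                        lp.loop_id,
                        lp.contact_a,
                        lp.contact_b,
                        f"{lp.log2fc:.6g}",
                        f"{lp.fdr:.6g}",
                    )
                )
                + "\n"
            )


class FeatureIndex:
    """Interval index over (feature_id, interval) pairs for >=1 bp overlap
    queries."""

    def __init__(self, features: Iterable[tuple[str, GenomicInterval]]):
        self._trees: dict[str, IntervalTree] = {}
        self.features = dict(features)
        for fid, iv in self.features.items():
            self._trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, fid)

    def query(self, region: GenomicInterval) -> set[str]:
        tree = self._trees.get(region.chrom)
        if tree is None:
            return set()
        return {hit.data for hit in tree.overlap(region.start, region.end)}

    def overlaps_any(self, region: GenomicInterval) -> bool:
        tree = self._trees.get(region.chrom)
        return bool(tree and tree.overlap(region.start, region.end))


def annotate_anchor(
    anchor: GenomicInterval,
    enhancers: FeatureIndex,
    promoters: FeatureIndex,
) -> tuple[set[str], set[str]]:
    """All enhancer and promoter features overlapping the anchor by >=1 bp."""
    return enhancers.query(anchor), promoters.query(anchor)


def classify_loop(
    loop: Loop,
    ann1: tuple[set[str], set[str]],
    ann2: tuple[set[str], set[str]],
) -> list[tuple[str, str | None, str | None]]:
    """Inclusive expansion of anchor annotations into typed feature pairs.

    Every cross-anchor pair is emitted, deduplicated order-insensitively,
    and typed EE / EP / PP by the kinds of its members (EP pairs are
    returned enhancer-first). If either anchor carries no feature a
    single ``("unassigned", None, None)`` record is returned.
    """
    side1 = [("E", fid) for fid in ann1[0]] + [("P", fid) for fid in ann1[1]]
    side2 = [("E", fid) for fid in ann2[0]] + [("P", fid) for fid in ann2[1]]
    if not side1 or not side2:
        return [("unassigned", None, None)]
    seen = set()
    out = []
    for f1 in sorted(side1):
        for f2 in sorted(side2):
            key = frozenset((f1, f2))
            if key in seen:
                continue
            seen.add(key)
            a, b = sorted((f1, f2))  # ("E", x) sorts before ("P", y)
            out.append((a[0] + b[0], a[1], b[1]))
    return out


def _lookup_diff(diff: pd.DataFrame, feature_id: str, what: str):
    if feature_id in diff.index:
        row = diff.loc[feature_id]
        return float(row["log2fc"]), float(row["fdr"])
    logger.warning("%s %s missing from differential table; flags recorded as missing", what, feature_id)
    return np.nan, np.nan


def _enriched(tables: Sequence[pd.DataFrame], feature_id: str, fdr_threshold: float):
    """Positive log2fc at fdr < threshold in any of the supplied patient
    comparison tables; missing from all tables -> pd.NA."""
    found = False
    for table in tables:
        if feature_id in table.index:
            found = True
            row = table.loc[feature_id]
            if float(row["log2fc"]) > 0 and float(row["fdr"]) < fdr_threshold:
                return True
    return False if found else pd.NA


def build_master_table(
    loops: Sequence[Loop],
    *,
    enhancers: FeatureIndex,
    promoters: FeatureIndex,
    enhancer_diff: pd.DataFrame,
    expression_diff: pd.DataFrame,
    p52_peaks: Sequence[GenomicInterval],
    consensus_ses: Sequence[ConsensusSE],
    stabilo_classes: Mapping[str, str],
    patient_epigenomic: pd.DataFrame | Sequence[pd.DataFrame],
    patient_expression: pd.DataFrame,
    essential_genes: set[str],
    fdr_threshold: float = FDR_THRESHOLD,
) -> pd.DataFrame:
    """Integrate EP pairs from (pre-filtered, significant) loops into the
    master table — one row per (loop, enhancer, gene) triple.

    ``enhancer_diff`` / ``expression_diff`` / patient tables are frames
    indexed by feature id with columns ``log2fc`` and ``fdr``. Patient
    enrichment = positive log2fc with fdr < ``fdr_threshold`` (OR across
    epigenomic assays when several tables are given).
    """
    if isinstance(patient_epigenomic, pd.DataFrame):
        epi_tables = [patient_epigenomic]
    else:
        epi_tables = list(patient_epigenomic)
    p52_index = FeatureIndex(
        (f"p52_{i}", iv) for i, iv in enumerate(p52_peaks)
    )
    rows = []
    for loop in loops:
        ann1 = annotate_anchor(loop.anchor1, enhancers, promoters)
        ann2 = annotate_anchor(loop.anchor2, enhancers, promoters)
        for ptype, f1, f2 in classify_loop(loop, ann1, ann2):
            if ptype != "EP":
                continue
            enh_id, gene_id = f1, f2
            enh_iv = enhancers.features[enh_id]
            enh_l2fc, enh_fdr = _lookup_diff(enhancer_diff, enh_id, "enhancer")
            gene_l2fc, gene_fdr = _lookup_diff(expression_diff, gene_id, "gene")
            if enh_id not in stabilo_classes:
                logger.warning("enhancer %s has no STABILO class; recorded missing", enh_id)
            rows.append(
                {
                    "loop_id": loop.loop_id,
                    "enhancer_id": enh_id,
                    "gene_id": gene_id,
                    "loop_log2fc": loop.log2fc,
                    "loop_fdr": loop.fdr,
                    "enhancer_log2fc": enh_l2fc,
                    "enhancer_fdr": enh_fdr,
                    "gene_log2fc": gene_l2fc,
                    "gene_fdr": gene_fdr,
                    "p52_bound": p52_index.overlaps_any(enh_iv),
                    "se_member": any(
                        se.interval.contains_point(enh_iv.chrom, enh_iv.midpoint)
                        for se in consensus_ses
                    ),
                    "stabilo_class": stabilo_classes.get(enh_id, pd.NA),
                    "nfkb_enriched_epigenome": _enriched(epi_tables, enh_id, fdr_threshold),
                    "nfkb_enriched_expression": _enriched(
                        [patient_expression], gene_id, fdr_threshold
                    ),
                    "essential": gene_id in essential_genes,
                }
            )
    table = pd.DataFrame(rows, columns=MASTER_COLUMNS)
    return table.sort_values(["loop_id", "enhancer_id", "gene_id"]).reset_index(drop=True)


def percent_half_up(k: int, n: int) -> int:
    """Integer percentage 100·k/n with exact round-half-up semantics."""
    if n <= 0:
        raise ValueError("denominator must be positive")
    if k < 0:
        raise ValueError("numerator must be >= 0")
    return (200 * k + n) // (2 * n)


def concordance_summary(
    records: pd.DataFrame, fdr_threshold: float = FDR_THRESHOLD
) -> dict:
    """Correlations and sign/significance categories across EPI records.

    Requires >= 3 records with both enhancer and gene dynamics present.
    Pearson/Spearman are between enhancer and gene log2 fold changes;
    categories count concordant/discordant sign pairs among records
    where both features are significant (fdr < threshold), with integer
    round-half-up percentages.
    """
    both = records.dropna(subset=["enhancer_log2fc", "gene_log2fc"])
    if len(both) < 3:
        raise ValueError("need at least 3 records with both dynamics present")
    x = both["enhancer_log2fc"].to_numpy(dtype=float)
    y = both["gene_log2fc"].to_numpy(dtype=float)
    if np.std(x) == 0 or np.std(y) == 0:
        pearson = spearman = None  # degenerate variance: undefined
    else:
        pearson = float(stats.pearsonr(x, y).statistic)
        spearman = float(stats.spearmanr(x, y).statistic)
    sig = both[(both["enhancer_fdr"] < fdr_threshold) & (both["gene_fdr"] < fdr_threshold)]
    counts = {
        "enh_down_gene_down": int(((sig["enhancer_log2fc"] < 0) & (sig["gene_log2fc"] < 0)).sum()),
        "enh_up_gene_up": int(((sig["enhancer_log2fc"] > 0) & (sig["gene_log2fc"] > 0)).sum()),
        "enh_down_gene_up": int(((sig["enhancer_log2fc"] < 0) & (sig["gene_log2fc"] > 0)).sum()),
        "enh_up_gene_down": int(((sig["enhancer_log2fc"] > 0) & (sig["gene_log2fc"] < 0)).sum()),
    }
    n_sig = len(sig)
    percentages = {
        k: (percent_half_up(v, n_sig) if n_sig else 0) for k, v in counts.items()
    }
    return {
        "n_records": int(len(both)),
        "n_both_significant": n_sig,
        "pearson": pearson,
        "spearman": spearman,
        "counts": counts,
        "percentages": percentages,
    }


def loop_diff_summary(loops_all: Sequence, loops_differential: Sequence) -> dict:
    """Totals, differential count, round-half-up percentage and the
    fraction of differential loops with negative log2fc."""
    n_total = len(loops_all)
    if n_total == 0:
        raise ValueError("no loops supplied")
    n_diff = len(loops_differential)
    if n_diff > n_total:
        raise ValueError("differential set larger than full set")
    log2fcs = [lp.log2fc for lp in loops_differential if hasattr(lp, "log2fc")]
    frac_negative = (
        sum(1 for v in log2fcs if v < 0) / len(log2fcs) if log2fcs else float("nan")
    )
    return {
        "n_total": n_total,
        "n_diff": n_diff,
        "percent": percent_half_up(n_diff, n_total),
        "frac_negative": frac_negative,
    }
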