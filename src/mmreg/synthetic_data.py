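"""Self-contained synthetic corpus with planted ground truth.

The generator emits every input the pipeline consumes — gene models,
multi-stage chromHMM segmentations, replicate H3K27ac peak files, p52
consensus peaks, an expression cohort, externally-computed differential
tables, patient comparison tables, an essential-gene list and a HiChIP
loop table — alongside ground-truth tables for each downstream stage
(enhancer-origin class per locus, NF-κB group per sample, SE status per
region, loop type per loop and the expected EPI master table).

Layout: each chromosome is divided into 20 kb slots. Slot ``s`` holds a
1 kb enhancer locus at offset 4000 (consensus peak = central 500 bp),
optional satellite peaks at ±3 kb of the locus midpoint (only at
super-enhancer sites, so stitched clusters stay > 12.5 kb apart) and a
gene with TSS at offset 14000 for the first gene-bearing slots. This
keeps every anchor/feature overlap unambiguous at the default settings.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .intervals import GenomicInterval
from .nfkb_index import DEFAULT_SIGNATURE, GROUP_MINUS, GROUP_PLUS

logger = logging.getLogger(__name__)

# slot geometry (bp)
SLOT = 20_000
LOCUS_OFFSET = 4_000
LOCUS_LEN = 1_000
SAT_OFFSET = 3_000  # satellite centres relative to locus midpoint
SAT_HALF = 250
TSS_OFFSET = 14_000
GENE_LEN = 3_000

STABILO_CLASSES = ("de_novo", "reactivated", "preserved", "lost", "unknown")

TRUTH_DIR = "truth"


@dataclass
class GeneratorConfig:
    """Study conditions for the synthetic corpus."""

    seed: int = 0
    n_chroms: int = 2
    chrom_length: int = 5_000_000
    n_genes: int = 200
    n_loci: int = 500
    class_proportions: dict = field(
        default_factory=lambda: {
            "de_novo": 0.25,
            "reactivated": 0.20,
            "preserved": 0.25,
            "lost": 0.15,
            "unknown": 0.15,
        }
    )
    n_samples_per_group: dict = field(default_factory=lambda: {"B": 3, "PC": 3, "MM": 3})
    cohort_size: int = 60
    fraction_nfkb_plus: float = 0.5
    signature_effect: float = 1.5
    expression_noise_sd: float = 0.3
    peak_signal_noise_sd: float = 0.1
    n_se_sites: int = 40
    n_loops: int = 150
    loop_type_proportions: dict = field(
        default_factory=lambda: {"EE": 0.33, "EP": 0.46, "PP": 0.21}
    )
    frac_loops_significant: float = 0.85
    frac_loops_negative: float = 2 / 3
    p52_fraction: float = 0.4
    essential_fraction: float = 0.15
    enhancer_down_fraction: float = 0.55
    enhancer_up_fraction: float = 0.30
    effect_log2fc_mean: float = 2.0
    effect_log2fc_sd: float = 0.4
    gene_effect_slope: float = 0.8
    gene_effect_noise_sd: float = 0.4
    boundary_jitter_bp: int = 0
    active_states: tuple = ("E9", "E10")
    background_state: str = "E1"
    fdr_threshold: float = 0.1

    def __post_init__(self):
        if set(self.class_proportions) != set(STABILO_CLASSES):
            raise ValueError(
                "class_proportions must give a value for each of the 5 classes"
            )
        if abs(sum(self.class_proportions.values()) - 1) > 1e-9:
            raise ValueError("class_proportions must sum to 1")
        if abs(sum(self.loop_type_proportions.values()) - 1) > 1e-9:
            raise ValueError("loop_type_proportions must sum to 1")
        if self.n_loci % self.n_chroms or self.n_genes % self.n_chroms:
            raise ValueError("n_loci and n_genes must be divisible by n_chroms")
        slots = self.chrom_length // SLOT
        if self.n_loci // self.n_chroms > slots:
            raise ValueError("too many loci for chromosome length")
        if self.n_genes < len(DEFAULT_SIGNATURE) + 1:
            raise ValueError("need at least 12 genes")
        if self.n_genes > self.n_loci:
            raise ValueError("layout places at most one gene per locus slot")
        if not self.n_samples_per_group.get("MM"):
            raise ValueError("MM group needs at least one sample")


@dataclass
class GroundTruth:
    """Planted truth for every pipeline stage."""

    loci: pd.DataFrame
    samples: pd.DataFrame
    se: pd.DataFrame
    loops: pd.DataFrame
    master: pd.DataFrame


def _chrom_name(i: int) -> str:
    return f"chr{i + 1}"


def _locus_interval(chrom: str, slot: int) -> GenomicInterval:
    base = slot * SLOT
    return GenomicInterval(chrom, base + LOCUS_OFFSET, base + LOCUS_OFFSET + LOCUS_LEN)


def _consensus_interval(locus: GenomicInterval) -> GenomicInterval:
    mid = locus.midpoint
    return GenomicInterval(locus.chrom, mid - 250, mid + 250)


def _tss(slot: int) -> int:
    return slot * SLOT + TSS_OFFSET


def _write_tsv(df: pd.DataFrame, path, index=False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format="%.6g")


# ---------------------------------------------------------------------------
# component builders (also used directly by tests)
# ---------------------------------------------------------------------------

def make_gene_ids(n_genes: int) -> list[str]:
    """Signature genes first, then synthetic symbols."""
    extra = [f"GENE{i:04d}" for i in range(len(DEFAULT_SIGNATURE), n_genes)]
    return list(DEFAULT_SIGNATURE) + extra


def make_expression_cohort(
    cfg: GeneratorConfig, rng: np.random.Generator
) -> tuple[pd.DataFrame, pd.Series]:
    """Log-normal expression cohort with the signature multiplicatively
    shifted in NF-κB+ samples; returns (genes x samples frame, true groups)."""
    gene_ids = make_gene_ids(cfg.n_genes)
    samples = [f"P{i + 1:03d}" for i in range(cfg.cohort_size)]
    n_plus = round(cfg.cohort_size * cfg.fraction_nfkb_plus)
    perm = rng.permutation(cfg.cohort_size)
    plus = np.zeros(cfg.cohort_size, dtype=bool)
    plus[perm[:n_plus]] = True
    base = rng.normal(2.0, 0.5, size=cfg.n_genes)
    noise = rng.normal(0.0, cfg.expression_noise_sd, size=(cfg.n_genes, cfg.cohort_size))
    values = np.exp(base[:, None] + noise)
    sig_rows = [gene_ids.index(g) for g in DEFAULT_SIGNATURE]
    values[np.ix_(sig_rows, np.where(plus)[0])] *= cfg.signature_effect
    expr = pd.DataFrame(values, index=pd.Index(gene_ids, name="gene"), columns=samples)
    groups = pd.Series(
        np.where(plus, GROUP_PLUS, GROUP_MINUS), index=samples, name="group"
    )
    return expr, groups


def _plant_activity(cls: str, rng: np.random.Generator) -> tuple[bool, bool, bool]:
    if cls == "de_novo":
        return False, False, True
    if cls == "reactivated":
        return True, False, True
    if cls == "preserved":
        return bool(rng.random() < 0.5), True, True
    if cls == "lost":
        return [(True, True, False), (True, False, False), (False, True, False)][
            int(rng.integers(3))
        ]
    return False, False, False


def _active_sample_mask(n: int, rng: np.random.Generator) -> np.ndarray:
    mask = rng.random(n) < 0.7
    if not mask.any():
        mask[int(rng.integers(n))] = True
    return mask


# ---------------------------------------------------------------------------
# generate
# ---------------------------------------------------------------------------

def generate(cfg: GeneratorConfig, outdir) -> GroundTruth:
    """Write the full corpus + truth tables to ``outdir``; returns truth.

    Deterministic: a fixed seed yields byte-identical output directories.
    """
    outdir = Path(outdir)
    (outdir / "segmentations").mkdir(parents=True, exist_ok=True)
    (outdir / "peaks").mkdir(exist_ok=True)
    (outdir / TRUTH_DIR).mkdir(exist_ok=True)
    rng = np.random.default_rng(cfg.seed)

    loci_per_chrom = cfg.n_loci // cfg.n_chroms
    genes_per_chrom = cfg.n_genes // cfg.n_chroms

    # ---- loci ------------------------------------------------------------
    classes = rng.choice(
        STABILO_CLASSES,
        size=cfg.n_loci,
        p=[cfg.class_proportions[c] for c in STABILO_CLASSES],
    )
    se_loci = set(rng.choice(cfg.n_loci, size=cfg.n_se_sites, replace=False).tolist())
    loci = []
    for i in range(cfg.n_loci):
        chrom = _chrom_name(i // loci_per_chrom)
        slot = i % loci_per_chrom
        iv = _locus_interval(chrom, slot)
        b, pc, mm = _plant_activity(str(classes[i]), rng)
        # planted differential effect on the enhancer
        u = rng.random()
        if u < cfg.enhancer_down_fraction:
            category = "down"
            log2fc = -abs(rng.normal(cfg.effect_log2fc_mean, cfg.effect_log2fc_sd))
        elif u < cfg.enhancer_down_fraction + cfg.enhancer_up_fraction:
            category = "up"
            log2fc = abs(rng.normal(cfg.effect_log2fc_mean, cfg.effect_log2fc_sd))
        else:
            category = "null"
            log2fc = rng.normal(0.0, 0.15)
        fdr = (
            rng.uniform(1e-6, 0.05) if category != "null" else rng.uniform(0.2, 0.95)
        )
        loci.append(
            {
                "idx": i,
                "chrom": chrom,
                "slot": slot,
                "interval": iv,
                "enhancer_id": _consensus_interval(iv).name,
                "stabilo_class": str(classes[i]),
                "b_active": b,
                "pc_active": pc,
                "mm_active": mm,
                "is_se": i in se_loci,
                "p52_bound": bool(rng.random() < cfg.p52_fraction),
                "category": category,
                "log2fc": float(log2fc),
                "fdr": float(fdr),
            }
        )

    # ---- genes -----------------------------------------------------------
    gene_ids = make_gene_ids(cfg.n_genes)
    genes = []
    for gi, gid in enumerate(gene_ids):
        chrom_i = gi // genes_per_chrom
        slot = gi % genes_per_chrom
        chrom = _chrom_name(chrom_i)
        strand = "+" if rng.random() < 0.5 else "-"
        tss = _tss(slot)
        if strand == "+":
            body = GenomicInterval(chrom, tss, tss + GENE_LEN)
            exons = [(tss, tss + 500), (tss + GENE_LEN - 500, tss + GENE_LEN)]
        else:
            body = GenomicInterval(chrom, tss - GENE_LEN + 1, tss + 1)
            exons = [(tss - GENE_LEN + 1, tss - GENE_LEN + 501), (tss - 499, tss + 1)]
        genes.append(
            {
                "gene_id": gid,
                "chrom": chrom,
                "chrom_i": chrom_i,
                "slot": slot,
                "strand": strand,
                "tss": tss,
                "body": body,
                "exons": exons,
                "essential": bool(rng.random() < cfg.essential_fraction),
                "expr_log2fc": None,  # filled by EP loop planting / nulls
                "expr_fdr": None,
            }
        )
    gene_by_pos = {(g["chrom_i"], g["slot"]): g for g in genes}

    # ---- segmentations ---------------------------------------------------
    group_samples = {
        grp: [f"{grp}_{k + 1}" for k in range(cfg.n_samples_per_group.get(grp, 0))]
        for grp in ("B", "PC", "MM")
    }
    # which samples realize each active locus (any-sample rule)
    active_by_sample: dict[str, list[GenomicInterval]] = {
        s: [] for ss in group_samples.values() for s in ss
    }
    flag = {"B": "b_active", "PC": "pc_active", "MM": "mm_active"}
    for loc in loci:
        for grp in ("B", "PC", "MM"):
            samples = group_samples[grp]
            if not samples or not loc[flag[grp]]:
                continue
            mask = _active_sample_mask(len(samples), rng)
            for s, on in zip(samples, mask):
                if on:
                    active_by_sample[s].append(loc["interval"])

    seg_files: dict[str, list[str]] = {g: [] for g in ("B", "PC", "MM")}
    j = cfg.boundary_jitter_bp
    for grp in ("B", "PC", "MM"):
        for sample in group_samples[grp]:
            rel = f"segmentations/{sample}.bed"
            seg_files[grp].append(rel)
            with open(outdir / rel, "w") as fh:
                for ci in range(cfg.n_chroms):
                    chrom = _chrom_name(ci)
                    actives = sorted(
                        (iv for iv in active_by_sample[sample] if iv.chrom == chrom),
                        key=lambda iv: iv.start,
                    )
                    pos = 0
                    for iv in actives:
                        s, e = iv.start, iv.end
                        if j:
                            s += int(rng.integers(-j, j + 1))
                            e += int(rng.integers(-j, j + 1))
                        state = str(rng.choice(cfg.active_states))
                        if s > pos:
                            fh.write(f"{chrom}\t{pos}\t{s}\t{cfg.background_state}\n")
                        fh.write(f"{chrom}\t{s}\t{e}\t{state}\n")
                        pos = e
                    fh.write(f"{chrom}\t{pos}\t{cfg.chrom_length}\t{cfg.background_state}\n")
    with open(outdir / "sample_groups.tsv", "w") as fh:
        for grp in ("B", "PC", "MM"):
            for sample in group_samples[grp]:
                fh.write(f"{sample}\t{grp}\n")

    # ---- genes.gtf --------------------------------------------------------
    with open(outdir / "genes.gtf", "w") as fh:
        for g in sorted(genes, key=lambda g: (g["chrom"], g["body"].start, g["gene_id"])):
            attrs = f'gene_id "{g["gene_id"]}";'
            fh.write(
                f'{g["chrom"]}\tmmreg\tgene\t{g["body"].start + 1}\t{g["body"].end}\t.'
                f'\t{g["strand"]}\t.\t{attrs}\n'
            )
            for (es, ee) in g["exons"]:
                fh.write(
                    f'{g["chrom"]}\tmmreg\texon\t{es + 1}\t{ee}\t.'
                    f'\t{g["strand"]}\t.\t{attrs}\n'
                )

    # ---- expression cohort -------------------------------------------------
    expr, cohort_groups = make_expression_cohort(cfg, rng)
    expr.to_csv(outdir / "expression.tsv", sep="\t", float_format="%.6g")

    # ---- peaks (H3K27ac replicates, ctrl + kd) -----------------------------
    peak_records = []  # (chrom, start, end, peak_id, ctrl_base, log2fc)
    for loc in loci:
        mid = loc["interval"].midpoint
        if loc["is_se"]:
            # strong separation from typical enhancers so the planted SE set
            # is exactly recoverable by the tangent cutoff at any seed
            bases = np.exp(rng.normal(np.log(10_000.0), 0.1, size=3))
            centres = (mid - SAT_OFFSET, mid, mid + SAT_OFFSET)
            for k, (c, base) in enumerate(zip(centres, bases)):
                if k == 1:
                    iv, pid, l2 = loc["interval"], f"peak_{loc['idx']:04d}", loc["log2fc"]
                else:
                    iv = GenomicInterval(loc["chrom"], c - SAT_HALF, c + SAT_HALF)
                    pid = f"peak_{loc['idx']:04d}_sat{k}"
                    l2 = loc["log2fc"] + float(rng.normal(0.0, 0.1))
                peak_records.append((iv, pid, float(base), l2))
        else:
            base = float(rng.uniform(5.0, 20.0))
            peak_records.append(
                (loc["interval"], f"peak_{loc['idx']:04d}", base, loc["log2fc"])
            )
    peak_records.sort(key=lambda r: (r[0].chrom, r[0].start))
    peak_files: dict[str, list[str]] = {"ctrl": [], "kd": []}
    for cond in ("ctrl", "kd"):
        for rep in (1, 2):
            rel = f"peaks/h3k27ac_{cond}_rep{rep}.bed"
            peak_files[cond].append(rel)
            with open(outdir / rel, "w") as fh:
                for iv, pid, base, l2 in peak_records:
                    signal = base * (2.0 ** l2 if cond == "kd" else 1.0)
                    signal *= float(np.exp(rng.normal(0.0, cfg.peak_signal_noise_sd)))
                    fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{pid}\t{signal:.4f}\n")

    # ---- p52 consensus peaks ----------------------------------------------
    with open(outdir / "p52_consensus.bed", "w") as fh:
        for loc in loci:
            if loc["p52_bound"]:
                civ = _consensus_interval(loc["interval"])
                fh.write(f"{civ.chrom}\t{civ.start}\t{civ.end}\tp52_{loc['idx']:04d}\n")

    # ---- enhancer differential table ---------------------------------------
    enh_rows = []
    for iv, pid, base, l2 in peak_records:
        civ_name = GenomicInterval(iv.chrom, iv.midpoint - 250, iv.midpoint + 250).name
        is_locus = not pid.endswith(("sat0", "sat2"))
        if is_locus:
            loc = loci[int(pid.split("_")[1])]
            fdr = loc["fdr"]
        else:
            loc = loci[int(pid.split("_")[1])]
            fdr = (
                rng.uniform(1e-6, 0.05)
                if loc["category"] != "null"
                else rng.uniform(0.2, 0.95)
            )
        enh_rows.append(
            {
                "feature_id": civ_name,
                "log2fc": l2,
                "pvalue": fdr * 0.5,
                "fdr": fdr,
            }
        )
    enh_diff = pd.DataFrame(enh_rows)
    _write_tsv(enh_diff, outdir / "enhancer_diff.tsv")

    # ---- patient comparison tables (epigenomic x2, expression) -------------
    epi_truth: dict[str, bool] = {}
    epi_tables = {"patient_h3k27ac.tsv": [], "patient_atac.tsv": []}
    for loc in loci:
        enriched_any = bool(rng.random() < 0.5)
        if enriched_any:
            in1 = bool(rng.random() < 0.7)
            in2 = bool(rng.random() < 0.7)
            if not (in1 or in2):
                in1 = True
        else:
            in1 = in2 = False
        epi_truth[loc["enhancer_id"]] = enriched_any
        for fname, flag_on in (("patient_h3k27ac.tsv", in1), ("patient_atac.tsv", in2)):
            if flag_on:
                l2, fdr = rng.uniform(0.5, 3.0), rng.uniform(1e-5, 0.05)
            elif rng.random() < 0.5:
                l2, fdr = rng.uniform(-3.0, -0.2), rng.uniform(1e-5, 0.05)
            else:
                l2, fdr = rng.uniform(0.2, 3.0), rng.uniform(0.15, 0.95)
            epi_tables[fname].append(
                {"feature_id": loc["enhancer_id"], "log2fc": l2, "fdr": fdr}
            )
    for fname, rows in epi_tables.items():
        _write_tsv(pd.DataFrame(rows), outdir / fname)

    expr_truth: dict[str, bool] = {}
    pat_expr_rows = []
    for g in genes:
        enriched = bool(rng.random() < 0.5)
        expr_truth[g["gene_id"]] = enriched
        if enriched:
            l2, fdr = rng.uniform(0.5, 3.0), rng.uniform(1e-5, 0.05)
        elif rng.random() < 0.5:
            l2, fdr = rng.uniform(-3.0, -0.2), rng.uniform(1e-5, 0.05)
        else:
            l2, fdr = rng.uniform(0.2, 3.0), rng.uniform(0.15, 0.95)
        pat_expr_rows.append({"feature_id": g["gene_id"], "log2fc": l2, "fdr": fdr})
    _write_tsv(pd.DataFrame(pat_expr_rows), outdir / "patient_expression.tsv")

    with open(outdir / "essential_genes.txt", "w") as fh:
        for g in genes:
            if g["essential"]:
                fh.write(g["gene_id"] + "\n")

    # ---- loops --------------------------------------------------------------
    loop_types = rng.choice(
        ["EE", "EP", "PP"],
        size=cfg.n_loops,
        p=[cfg.loop_type_proportions[t] for t in ("EE", "EP", "PP")],
    )
    loci_by_pos = {(l["idx"] // loci_per_chrom, l["slot"]): l for l in loci}
    available_genes = {
        ci: [g["slot"] for g in genes if g["chrom_i"] == ci] for ci in range(cfg.n_chroms)
    }
    loop_rows = []
    truth_loop_rows = []
    truth_master_rows = []

    def _anchor(chrom: str, centre: int) -> GenomicInterval:
        return GenomicInterval(chrom, centre - 1250, centre + 1250)

    for li, ltype in enumerate(map(str, loop_types)):
        loop_id = f"L{li + 1:04d}"
        ci = int(rng.integers(cfg.n_chroms))
        chrom = _chrom_name(ci)
        if ltype == "EP":
            pool = available_genes[ci] or [g["slot"] for g in genes if g["chrom_i"] == ci]
            jslot = int(pool[int(rng.integers(len(pool)))])
            if jslot in available_genes[ci]:
                available_genes[ci].remove(jslot)
            cands = [
                s
                for s in range(max(0, jslot - 50), min(loci_per_chrom - 1, jslot + 50) + 1)
                if s != jslot
            ]
            eslot = int(cands[int(rng.integers(len(cands)))])
            enh = loci_by_pos[(ci, eslot)]
            gene = gene_by_pos[(ci, jslot)]
            a1 = _anchor(chrom, enh["interval"].midpoint)
            a2 = _anchor(chrom, gene["tss"])
            features = ("EP", enh, gene)
        elif ltype == "EE":
            delta = int(rng.integers(1, min(50, loci_per_chrom - 1) + 1))
            s1 = int(rng.integers(loci_per_chrom - delta))
            s2 = s1 + delta
            e1, e2 = loci_by_pos[(ci, s1)], loci_by_pos[(ci, s2)]
            a1 = _anchor(chrom, e1["interval"].midpoint)
            a2 = _anchor(chrom, e2["interval"].midpoint)
            features = ("EE", e1, e2)
        else:  # PP
            delta = int(rng.integers(1, min(50, genes_per_chrom - 1) + 1))
            j1 = int(rng.integers(genes_per_chrom - delta))
            j2 = j1 + delta
            g1, g2 = gene_by_pos[(ci, j1)], gene_by_pos[(ci, j2)]
            a1 = _anchor(chrom, g1["tss"])
            a2 = _anchor(chrom, g2["tss"])
            features = ("PP", g1, g2)

        significant = bool(rng.random() < cfg.frac_loops_significant)
        if significant:
            sign = -1.0 if rng.random() < cfg.frac_loops_negative else 1.0
            l2fc = sign * abs(rng.normal(1.5, 0.5))
            fdr = rng.uniform(1e-6, 0.05)
        else:
            l2fc = rng.normal(0.0, 0.2)
            fdr = rng.uniform(0.2, 0.9)
        contact_a = int(rng.integers(10, 200))
        contact_b = max(0, int(round(contact_a * 2.0 ** l2fc)))
        loop_rows.append(
            (chrom, a1.start, a1.end, chrom, a2.start, a2.end, loop_id, contact_a,
             contact_b, f"{l2fc:.6g}", f"{fdr:.6g}")
        )
        truth_loop_rows.append(
            {
                "loop_id": loop_id,
                "loop_type": ltype,
                "significant": significant,
                "log2fc_sign": "neg" if l2fc < 0 else "pos",
            }
        )

        if ltype == "EP":
            _, enh, gene = features
            if gene["expr_log2fc"] is None:
                g_l2 = cfg.gene_effect_slope * enh["log2fc"] + float(
                    rng.normal(0.0, cfg.gene_effect_noise_sd)
                )
                g_fdr = (
                    rng.uniform(1e-6, 0.05)
                    if enh["category"] != "null"
                    else rng.uniform(0.2, 0.9)
                )
                gene["expr_log2fc"], gene["expr_fdr"] = float(g_l2), float(g_fdr)
            if fdr <= cfg.fdr_threshold:
                truth_master_rows.append(
                    {
                        "loop_id": loop_id,
                        "enhancer_id": enh["enhancer_id"],
                        "gene_id": gene["gene_id"],
                        "loop_log2fc": float(f"{l2fc:.6g}"),
                        "loop_fdr": float(f"{fdr:.6g}"),
                        "enhancer_log2fc": enh["log2fc"],
                        "enhancer_fdr": enh["fdr"],
                        "gene_log2fc": gene["expr_log2fc"],
                        "gene_fdr": gene["expr_fdr"],
                        "p52_bound": enh["p52_bound"],
                        "se_member": enh["is_se"],
                        "stabilo_class": enh["stabilo_class"],
                        "nfkb_enriched_epigenome": epi_truth[enh["enhancer_id"]],
                        "nfkb_enriched_expression": expr_truth[gene["gene_id"]],
                        "essential": gene["essential"],
                    }
                )

    with open(outdir / "loops.bedpe", "w") as fh:
        for row in loop_rows:
            fh.write("\t".join(str(x) for x in row) + "\n")

    # ---- expression differential table (fill remaining genes with nulls) ---
    expr_diff_rows = []
    for g in genes:
        if g["expr_log2fc"] is None:
            g["expr_log2fc"] = float(rng.normal(0.0, 0.3))
            g["expr_fdr"] = float(rng.uniform(0.2, 0.95))
        expr_diff_rows.append(
            {
                "feature_id": g["gene_id"],
                "log2fc": g["expr_log2fc"],
                "pvalue": g["expr_fdr"] * 0.5,
                "fdr": g["expr_fdr"],
            }
        )
    _write_tsv(pd.DataFrame(expr_diff_rows), outdir / "expression_diff.tsv")

    # ---- truth tables --------------------------------------------------------
    truth_loci = pd.DataFrame(
        {
            "locus_id": [l["enhancer_id"] for l in loci],
            "chrom": [l["chrom"] for l in loci],
            "start": [l["interval"].start for l in loci],
            "end": [l["interval"].end for l in loci],
            "b_active": [l["b_active"] for l in loci],
            "pc_active": [l["pc_active"] for l in loci],
            "mm_active": [l["mm_active"] for l in loci],
            "stabilo_class": [l["stabilo_class"] for l in loci],
        }
    )
    truth_samples = pd.DataFrame(
        {"sample": cohort_groups.index, "group": cohort_groups.to_numpy()}
    )
    truth_se = pd.DataFrame(
        {
            "enhancer_id": [l["enhancer_id"] for l in loci],
            "se_member": [l["is_se"] for l in loci],
        }
    )
    truth_loops = pd.DataFrame(truth_loop_rows)
    truth_master = (
        pd.DataFrame(truth_master_rows)
        .sort_values(["loop_id", "enhancer_id", "gene_id"])
        .reset_index(drop=True)
    )
    _write_tsv(truth_loci, outdir / TRUTH_DIR / "truth_loci.tsv")
    _write_tsv(truth_samples, outdir / TRUTH_DIR / "truth_samples.tsv")
    _write_tsv(truth_se, outdir / TRUTH_DIR / "truth_se.tsv")
    _write_tsv(truth_loops, outdir / TRUTH_DIR / "truth_loops.tsv")
    _write_tsv(truth_master, outdir / TRUTH_DIR / "truth_master.tsv")

    manifest = {
        "format": "mmreg-synthetic-v1",
        "seed": cfg.seed,
        "active_states": list(cfg.active_states),
        "fdr_threshold": cfg.fdr_threshold,
        "files": {
            "expression": "expression.tsv",
            "genes_gtf": "genes.gtf",
            "sample_groups": "sample_groups.tsv",
            "segmentations": seg_files,
            "h3k27ac_replicates": peak_files,
            "p52_peaks": "p52_consensus.bed",
            "enhancer_diff": "enhancer_diff.tsv",
            "expression_diff": "expression_diff.tsv",
            "patient_epigenomic": ["patient_h3k27ac.tsv", "patient_atac.tsv"],
            "patient_expression": "patient_expression.tsv",
            "essential_genes": "essential_genes.txt",
            "loops": "loops.bedpe",
            "truth_dir": TRUTH_DIR,
        },
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")

    return GroundTruth(truth_loci, truth_samples, truth_se, truth_loops, truth_master)


def load_truth(corpus_dir) -> GroundTruth:
    corpus_dir = Path(corpus_dir)
    t = corpus_dir / TRUTH_DIR

    def _read(name):
        return pd.read_csv(t / name, sep="\t")

    return GroundTruth(
        _read("truth_loci.tsv"),
        _read("truth_samples.tsv"),
        _read("truth_se.tsv"),
        _read("truth_loops.tsv"),
        _read("truth_master.tsv"),
    )


DEFAULT_THRESHOLDS = {
    "nfkb_group": 0.95,
    "stabilo_class": 0.95,
    "se_status": 0.95,
    "loop_type": 0.95,
    "master_rows": 1.0,
}


def validate_against_truth(
    run_dir, corpus_dir, thresholds: Mapping[str, float] | None = None
) -> dict:
    """Compare a pipeline output directory against the planted truth.

    Returns per-stage exact-agreement rates and pass flags; raises on
    structural (id) mismatches rather than reporting a low score.
    """
    run_dir, corpus_dir = Path(run_dir), Path(corpus_dir)
    truth = load_truth(corpus_dir)
    thr = dict(DEFAULT_THRESHOLDS)
    if thresholds:
        thr.update(thresholds)
    report: dict = {"agreement": {}, "passed": {}}

    # NF-kB groups
    idx = pd.read_csv(run_dir / "index.tsv", sep="\t").set_index("sample")
    t_samples = truth.samples.set_index("sample")
    if set(idx.index) != set(t_samples.index):
        raise ValueError("sample id mismatch between run output and truth")
    report["agreement"]["nfkb_group"] = float(
        (idx["group"] == t_samples["group"]).mean()
    )

    # STABILO classes (truth covers planted loci only)
    calls = pd.read_csv(run_dir / "stabilo_calls.tsv", sep="\t").set_index("locus_id")
    t_loci = truth.loci.set_index("locus_id")
    missing = set(t_loci.index) - set(calls.index)
    if missing:
        raise ValueError(f"{len(missing)} truth loci absent from stabilo calls")
    report["agreement"]["stabilo_class"] = float(
        (calls.loc[t_loci.index, "stabilo_class"] == t_loci["stabilo_class"]).mean()
    )

    # SE membership: locus midpoint inside any consensus SE region
    se_regions = []
    with open(run_dir / "consensus_se.bed") as fh:
        for line in fh:
            f = line.rstrip("\n").split("\t")
            if len(f) >= 3:
                se_regions.append((f[0], int(f[1]), int(f[2])))
    mids = ((t_loci["start"] + t_loci["end"]) // 2).to_numpy()
    member = np.zeros(len(t_loci), dtype=bool)
    for i, (chrom, mid) in enumerate(zip(t_loci["chrom"], mids)):
        member[i] = any(c == chrom and s <= mid < e for c, s, e in se_regions)
    t_se = truth.se.set_index("enhancer_id").loc[t_loci.index, "se_member"].to_numpy()
    report["agreement"]["se_status"] = float((member == t_se).mean())

    # loop types (significant loops only; pipeline classifies those)
    lt = pd.read_csv(run_dir / "loop_classes.tsv", sep="\t").set_index("loop_id")
    t_loops = truth.loops[truth.loops["significant"]].set_index("loop_id")
    missing = set(t_loops.index) - set(lt.index)
    if missing:
        raise ValueError(f"{len(missing)} significant truth loops absent from output")
    report["agreement"]["loop_type"] = float(
        (lt.loc[t_loops.index, "loop_type"] == t_loops["loop_type"]).mean()
    )

    # master table: row-by-row string equality after key sort
    got = pd.read_csv(run_dir / "master_table.tsv", sep="\t", dtype=str,
                      keep_default_na=False)
    want = pd.read_csv(corpus_dir / TRUTH_DIR / "truth_master.tsv", sep="\t",
                       dtype=str, keep_default_na=False)
    keys = ["loop_id", "enhancer_id", "gene_id"]
    got = got.sort_values(keys).reset_index(drop=True)
    want = want.sort_values(keys).reset_index(drop=True)
    if list(got.columns) != list(want.columns):
        raise ValueError("master table column mismatch")
    if len(got) != len(want):
        raise ValueError(
            f"master table row count mismatch: got {len(got)}, expected {len(want)}"
        )
    report["agreement"]["master_rows"] = float((got == want).all(axis=1).mean())

    for stage, rate in report["agreement"].items():
        report["passed"][stage] = bool(rate >= thr[stage])
    report["all_passed"] = all(report["passed"].values())
    return report
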