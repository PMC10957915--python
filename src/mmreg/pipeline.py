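"""End-to-end orchestration over a corpus directory with a manifest.

Stages run in dependency order: replicate consensus peaks -> NF-κB
indexing ∥ STABILO classification ∥ super-enhancer calling -> loop
integration and the EPI master table. Every run records the parameter
set and input checksums next to the outputs; fixed inputs and parameters
yield byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import pandas as pd

from . import intervals, loop_integration, nfkb_index, stabilo, superenhancer

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All tunables, defaulting to the study's published values."""

    stitch_distance: int = 12_500
    tss_exclusion: int = 2_500
    anchor_width: int = 2_500
    min_loop_distance: int = 10_000
    max_loop_distance: int = 2_000_000
    consensus_peak_width: int = 500
    min_replicate_support: int = 2
    overlap_fraction: float = 0.5
    fdr_threshold: float = 0.1
    promoter_up: int = 2_000
    promoter_down: int = 500
    nearest_n: int = 5
    active_states: tuple = ("E9", "E10")
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.overlap_fraction <= 1):
            raise ValueError("overlap_fraction must be in (0, 1]")
        if not (0 < self.fdr_threshold <= 1):
            raise ValueError("fdr_threshold must be in (0, 1]")


class PipelineError(RuntimeError):
    """A stage failure, naming the stage and offending input."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _require(data_dir: Path, rel: str, stage: str) -> Path:
    p = data_dir / rel
    if not p.exists():
        raise PipelineError(stage, f"required input missing: {p}")
    return p


def _read_diff_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    return df.set_index("feature_id")


def run_all(data_dir, out_dir, config: PipelineConfig | None = None) -> dict:
    """Run every stage on a corpus directory; returns a summary dict."""
    cfg = config or PipelineConfig()
    data_dir, out_dir = Path(data_dir), Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log_handler = logging.FileHandler(out_dir / "run.log", mode="w")
    log_handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    root = logging.getLogger("mmreg")
    root.addHandler(log_handler)
    checksums: dict[str, str] = {}
    try:
        manifest_path = _require(data_dir, "manifest.json", "setup")
        with open(manifest_path) as fh:
            manifest = json.load(fh)
        files = manifest["files"]

        def _input(rel: str, stage: str) -> Path:
            p = _require(data_dir, rel, stage)
            checksums[rel] = _sha256(p)
            return p

        # ---- gene models ---------------------------------------------------
        genes = intervals.read_gtf(_input(files["genes_gtf"], "intervals"))

        # ---- consensus peaks from control replicates -----------------------
        rep_paths = [
            _input(rel, "intervals") for rel in files["h3k27ac_replicates"]["ctrl"]
        ]
        rep_peaks = [intervals.read_bed(p) for p in rep_paths]
        cpeaks = intervals.consensus_peaks(rep_peaks, cfg.min_replicate_support)
        cpeaks = [
            intervals.ConsensusPeak(
                cp.interval,
                cp.support,
                intervals.annotate_feature_class(
                    cp.interval, genes, cfg.promoter_up, cfg.promoter_down
                ),
            )
            for cp in cpeaks
        ]
        intervals.write_bed(
            out_dir / "consensus_peaks.bed",
            (
                (cp.interval.chrom, cp.interval.start, cp.interval.end,
                 cp.interval.name, cp.support, cp.feature_class)
                for cp in cpeaks
            ),
        )

        # ---- NF-κB indexing --------------------------------------------------
        expr = nfkb_index.read_expression(_input(files["expression"], "nfkb_index"))
        index_result = nfkb_index.index_cohort(expr)
        nfkb_index.write_index(index_result, out_dir / "index.tsv")

        # ---- STABILO ---------------------------------------------------------
        state_cfg = stabilo.StateConfig(
            frozenset(manifest.get("active_states", cfg.active_states)),
            cfg.overlap_fraction,
        )
        groups = stabilo.read_manifest(_input(files["sample_groups"], "stabilo"))
        samples_by_group: dict[str, list[stabilo.Segmentation]] = {g: [] for g in stabilo.GROUPS}
        for grp, rels in files["segmentations"].items():
            for rel in rels:
                seg = stabilo.read_segmentation(_input(rel, "stabilo"))
                declared = groups.get(seg.sample_id, grp)
                samples_by_group[declared].append(seg)
        loci = {cp.interval.name: cp.interval for cp in cpeaks}
        calls = stabilo.classify_loci(loci, samples_by_group, state_cfg)
        calls.to_csv(out_dir / "stabilo_calls.tsv", sep="\t")

        # ---- super-enhancers --------------------------------------------------
        params = superenhancer.StitchParams(cfg.stitch_distance, cfg.tss_exclusion)
        per_sample_ses = {}
        for rel, peaks in zip(files["h3k27ac_replicates"]["ctrl"], rep_peaks):
            regions = superenhancer.call_superenhancers(peaks, genes, params)
            per_sample_ses[Path(rel).stem] = [r for r in regions if r.is_super]
        cons_ses = superenhancer.consensus_se(per_sample_ses)
        cons_ses = superenhancer.assign_constituents(cons_ses, cpeaks)
        intervals.write_bed(
            out_dir / "consensus_se.bed",
            (
                (se.interval.chrom, se.interval.start, se.interval.end,
                 ",".join(sorted(se.member_samples)),
                 len(se.constituent_consensus_peaks))
                for se in cons_ses
            ),
        )

        # ---- loop integration ---------------------------------------------------
        loops = loop_integration.read_bedpe(_input(files["loops"], "loop_integration"))
        sig_loops = [lp for lp in loops if lp.fdr <= cfg.fdr_threshold]
        enh_diff = _read_diff_table(_input(files["enhancer_diff"], "loop_integration"))
        expr_diff = _read_diff_table(_input(files["expression_diff"], "loop_integration"))
        patient_epi = [
            _read_diff_table(_input(rel, "loop_integration"))
            for rel in files["patient_epigenomic"]
        ]
        patient_expr = _read_diff_table(
            _input(files["patient_expression"], "loop_integration")
        )
        with open(_input(files["essential_genes"], "loop_integration")) as fh:
            essential = {line.strip() for line in fh if line.strip()}
        p52_peaks = [
            p.interval for p in intervals.read_bed(_input(files["p52_peaks"], "loop_integration"))
        ]
        enh_index = loop_integration.FeatureIndex(
            (cp.interval.name, cp.interval) for cp in cpeaks
        )
        prom_index = loop_integration.FeatureIndex(
            (g.gene_id, intervals.promoter_window(g, cfg.promoter_up, cfg.promoter_down))
            for g in genes
        )
        stabilo_classes = calls["stabilo_class"].to_dict()
        master = loop_integration.build_master_table(
            sig_loops,
            enhancers=enh_index,
            promoters=prom_index,
            enhancer_diff=enh_diff,
            expression_diff=expr_diff,
            p52_peaks=p52_peaks,
            consensus_ses=cons_ses,
            stabilo_classes=stabilo_classes,
            patient_epigenomic=patient_epi,
            patient_expression=patient_expr,
            essential_genes=essential,
            fdr_threshold=cfg.fdr_threshold,
        )
        master.to_csv(out_dir / "master_table.tsv", sep="\t", index=False,
                      float_format="%.6g")

        # per-loop interaction types (for validation/reporting)
        lc_rows = []
        for lp in sig_loops:
            ann1 = loop_integration.annotate_anchor(lp.anchor1, enh_index, prom_index)
            ann2 = loop_integration.annotate_anchor(lp.anchor2, enh_index, prom_index)
            types = sorted({t for t, _, _ in loop_integration.classify_loop(lp, ann1, ann2)})
            lc_rows.append({"loop_id": lp.loop_id, "loop_type": ";".join(types)})
        pd.DataFrame(lc_rows).to_csv(out_dir / "loop_classes.tsv", sep="\t", index=False)

        # ---- summaries -----------------------------------------------------------
        loop_summary = loop_integration.loop_diff_summary(loops, sig_loops)
        try:
            concordance = loop_integration.concordance_summary(master, cfg.fdr_threshold)
        except ValueError as exc:
            concordance = {"error": str(exc)}
        summary = {
            "n_consensus_peaks": len(cpeaks),
            "n_consensus_se": len(cons_ses),
            "n_samples": int(len(index_result)),
            "n_nfkb_plus": int((index_result["group"] == nfkb_index.GROUP_PLUS).sum()),
            "stabilo_class_counts": calls["stabilo_class"].value_counts().to_dict(),
            "loops": loop_summary,
            "concordance": concordance,
            "n_master_rows": int(len(master)),
        }
        with open(out_dir / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=1, sort_keys=True)
            fh.write("\n")
        with open(out_dir / "params.json", "w") as fh:
            json.dump(
                {"config": asdict(cfg), "input_sha256": checksums},
                fh, indent=1, sort_keys=True,
            )
            fh.write("\n")
        return summary
    finally:
        root.removeHandler(log_handler)
        log_handler.close()
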