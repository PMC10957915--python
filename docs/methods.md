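# Methods

This note documents the models and procedures mmreg implements, the
parameter choices and their defaults, what the synthetic corpus does and
does not emulate, and the numerical decisions made where the design was
genuinely open.

## Coordinates and interval algebra

All coordinates are 0-based half-open (BED semantics); GTF input is
converted on read. Overlap coverage is union-based: when several state
segments or peaks cover a target, overlapping bases are counted once.
Consensus peaks across replicates are built by union-merging overlapping
or book-ended peaks from all replicates, keeping merged regions backed
by at least `min_replicate_support` (default 2) distinct replicates, and
resizing each to exactly 500 bp centred on `floor((start+end)/2)` of the
merged region (shifted right if that would cross coordinate 0). An
unsatisfiable support filter (more required replicates than supplied)
yields an empty result with a warning rather than an error.

Feature-class annotation is decided by the peak midpoint with priority
promoter > exonic > intronic > intergenic. The promoter window is
strand-aware: `[tss−up, tss+down)` on the plus strand and its mirror
`[tss−down+1, tss+up+1)` on the minus strand, clipped at 0; the default
−2000/+500 matches the promoter definition used for loop-anchor
annotation, since the upstream peak annotator's window is otherwise
unspecified. Nearest-gene assignment ranks genes on the peak's
chromosome by |TSS − peak midpoint| with lexicographic gene-id
tie-breaking for determinism (default n = 5).

## NF-κB index

The index is computed on already variance-stabilized, strictly positive
expression values; zeros are rejected rather than pseudocounted, because
the transform producing the input guarantees positivity and a silent
pseudocount would shift the geometric mean. Standardization uses the
sample (n−1) standard deviation over the input cohort — when only a
subset of a larger study is supplied, the z-scores are relative to that
subset. "Beyond the upper quartile" is a strict inequality against the
linear-interpolation (type 7) 75th percentile, the numpy/R default;
values exactly at the quartile do not qualify. Classification depends
only on the signature rows, so adding or rescaling non-signature genes
cannot change the groups.

## STABILO

Activity of a locus in one sample requires the union of active-state
segments to cover at least `min_fraction` of the *locus* (inclusive,
default 0.5). The 50% rule could alternatively be read as a fraction of
the state segment; fraction-of-target was chosen because the loci are
the fixed query regions while segment lengths are an artefact of the
segmentation granularity. Group activity uses the ∃ rule: one active
sample makes the group active. The class map is total over the 8
(B, PC, MM) combinations: `preserved` requires MM ∧ PC with the B-cell
status free (otherwise the MM ∧ PC ∧ ¬B cell combination would be
unclassifiable), `lost` absorbs the three "active before, inactive in
MM" combinations. State labels from dense-BED segmentations are
normalised by stripping everything after the first underscore
(`E9_StrongEnh` → `E9`); which labels count as active is configuration
(defaults `E9`/`E10`), never inferred from emission parameters.

## Super-enhancer calling

Stitched-region signal is the plain sum of constituent peak signals; no
input-track subtraction is performed because the package consumes
peak-level signal, not alignments. The tangent cutoff is the classic
signal-rank geometry: with signals sorted ascending y₁…yₙ and the chord
from (1, y₁) to (n, yₙ), the tangent index minimises yᵢ − s·i (the point
furthest below the chord), ties resolved to the largest index, and
super status is a strict `>` against the cutoff signal. ROSE ports vary
in these details; this formulation is fixed here and verified against an
independent geometric oracle and an affine-invariance property rather
than against any particular port bit-for-bit. Numerically the distance
is computed as `(yᵢ − y₁)(n−1) − (yₙ − y₁)·i`, which avoids the slope
division so that the two chord endpoints tie *exactly* in floating
point; concave or linear curves therefore resolve to the last index and
produce no super-enhancers, instead of flipping the whole call set on a
1-ulp difference. All-identical signals produce no supers (logged);
fewer than 3 regions is an error. Consensus SEs are the union-merge of
per-sample SEs, and sample re-assignment requires ≥ 50% of the
*original* sample SE length inside the consensus interval — measured on
the original SE, not the consensus, following the stated re-assignment
rule. Constituent consensus peaks attach to a consensus SE when their
midpoint falls inside it.

## Loop integration

Loops are cis, with 2 500 bp anchors and midpoint separation in
(10 kb, 2 Mb]. Significance is FDR ≤ 0.1. Anchor annotation uses ≥ 1 bp
overlap against enhancer features and promoter windows of *all* genes
(differential status is carried as a flag rather than used to restrict
annotation, so unassigned anchors remain distinguishable from
non-differential ones). Ambiguous anchors are expanded inclusively:
every cross-anchor feature pair is emitted, deduplicated
order-insensitively, and typed by member kinds; per-loop granularity is
retained, so one EP pair interacting through two loops contributes two
master-table rows (consistent with additive multi-loop effects on
transcription). The master table restricts to EP pairs and joins, per
row: loop statistics, the enhancer's H3K27ac dynamics, the gene's
expression dynamics, p52 occupancy (≥ 1 bp overlap with any p52
consensus peak), SE membership (enhancer midpoint inside a consensus
SE), STABILO class, patient enrichment flags (positive log2FC at
FDR < 0.1 in the supplied NF-κB+ vs NF-κB− comparison tables, OR-ed
across epigenomic assays when both H3K27ac and accessibility tables are
given) and essentiality. Features missing from a differential table are
recorded as missing and logged, never dropped.

Reported integer percentages use exact round-half-up arithmetic
(`(200k + n) // (2n)`), verified against all five published
count/percentage pairs. Concordance reports Pearson and Spearman
correlation between enhancer and gene log2 fold changes; degenerate
variance yields an undefined (None) correlation.

## Synthetic corpus

The generator emulates the *shapes* of the study's inputs with planted
truth, on a deliberately idealised genome: `n_chroms` = 2 chromosomes of
5 Mb divided into 20 kb slots. Each slot carries a 1 kb enhancer locus;
super-enhancer sites (default 40 of 500 loci) additionally carry two
500 bp satellite peaks at ±3 kb so that stitched clusters stay more than
12.5 kb apart and stitching truth is unambiguous. Genes (default 200,
the 11 signature symbols first) sit at slot offset 14 kb, far enough
from all peaks that TSS exclusion and promoter windows never clip
enhancer features. Loop anchors are centred on exactly one feature each,
with EE/EP/PP proportions 0.33/0.46/0.21 and ~85% of loops significant,
two thirds of those losing contacts — the proportions observed in the
study this pipeline is designed around.

Key planted effects and their defaults:

| parameter | default | meaning |
|---|---|---|
| `signature_effect` | 1.5 | multiplicative shift of signature genes in NF-κB+ samples (transformed scale) |
| `expression_noise_sd` | 0.3 | log-scale lognormal noise per gene × sample |
| `cohort_size` / `fraction_nfkb_plus` | 60 / 0.5 | cohort composition |
| class proportions | .25/.20/.25/.15/.15 | de novo / reactivated / preserved / lost / unknown |
| `effect_log2fc_mean` ± sd | 2.0 ± 0.4 | magnitude of planted differential H3K27ac effects |
| `gene_effect_slope`, noise | 0.8, 0.4 | gene log2FC = slope × enhancer log2FC + noise (concordant EP pairs) |
| `p52_fraction` | 0.4 | enhancers co-occupied by p52 |
| `boundary_jitter_bp` | 0 | uniform jitter on segmentation edges |

Typical-enhancer peak signal is bounded uniform(5, 20) and planted SE
constituents are lognormal(ln 10 000, 0.1). The SE/TE separation is
deliberately exaggerated: it guarantees the rank-curve chord slope
exceeds the entire typical-signal range, so the tangent index lands
exactly on the planted boundary and SE truth is recoverable at every
seed. Real H3K27ac rank curves are far noisier near the knee; passing
the recovery tests therefore demonstrates correctness of the calling
machinery, not robustness of SE calling on borderline real data. The
same caveat applies generally: the corpus has no overlapping features,
no trans or multi-feature anchors, no id mismatches and no missing
table entries, so recovery rates measure implementation fidelity, not
expected performance on sequencing data.

One planted-truth edge is intrinsic to the classification rule rather
than to the generator: with zero expression noise and a 50/50 cohort,
every NF-κB+ sample sits exactly at each signature gene's 75th
percentile, and the strict "beyond the quartile" test then classifies
all samples NF-κB−. Cohort-recovery checks therefore run at the default
noise level, where agreement is ~98–99% (the residual errors are
samples whose index lands near 0).

Determinism: all randomness flows from one `numpy` Generator seeded by
`seed`; a fixed seed yields byte-identical corpora (files are written
with fixed `%.6g` float formatting, which also makes pipeline TSV
round-trips byte-stable).

## Pipeline

Stages run as: consensus peaks → NF-κB indexing ∥ STABILO ∥
super-enhancers → loop integration. Consensus peaks and SE calling use
the control-condition replicates; knockdown replicate files are part of
the corpus but their differential content enters through the externally
computed tables, mirroring how negative-binomial differential testing is
out of scope and consumed as input. Stage failures abort with the stage
name and offending path; `params.json` records the full parameter set
and SHA-256 of every input consumed.

## Known limitations

- Differential statistics (DESeq2/DiffBind/DiffLoop equivalents) are
  consumed, never computed; garbage-in applies.
- SE signal is peak-level; no input subtraction or coverage
  quantification.
- STABILO group summarisation is ∃-based; a single noisy sample can
  activate a group. A quorum rule would need per-dataset calibration.
- The inclusive loop expansion can emit quadratically many pairs for
  promiscuous anchors; no cap is applied.
- `validate_against_truth` requires exact id agreement by design —
  structural mismatches raise instead of deflating scores.
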