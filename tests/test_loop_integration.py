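"""Loop anchor annotation, inclusive EE/EP/PP expansion, master table and
reporting summaries."""

import numpy as np
import pandas as pd
import pytest

from mmreg.intervals import GenomicInterval
from mmreg.loop_integration import (
    FeatureIndex,
    Loop,
    annotate_anchor,
    build_master_table,
    classify_loop,
    concordance_summary,
    loop_diff_summary,
    percent_half_up,
    read_bedpe,
    write_bedpe,
)
from mmreg.superenhancer import ConsensusSE


def anchor(centre, chrom="chr1"):
    return GenomicInterval(chrom, centre - 1250, centre + 1250)


def loop(c1, c2, loop_id="L1", log2fc=-1.0, fdr=0.01, chrom="chr1"):
    return Loop(loop_id, anchor(c1, chrom), anchor(c2, chrom), 50, 25, log2fc, fdr)


class TestLoopInvariants:
    def test_anchor_width_enforced(self):
        with pytest.raises(ValueError, match="width"):
            Loop("L", GenomicInterval("chr1", 0, 2000), anchor(50_000), 1, 1, 0.0, 0.5)

    def test_distance_bounds(self):
        with pytest.raises(ValueError, match="distance"):
            loop(20_000, 29_000)  # 9 kb < lower bound
        with pytest.raises(ValueError, match="distance"):
            loop(20_000, 2_500_000)
        loop(20_000, 31_000)  # 11 kb: fine

    def test_cis_only(self):
        with pytest.raises(ValueError, match="cis"):
            Loop("L", anchor(20_000, "chr1"), anchor(90_000, "chr2"), 1, 1, 0.0, 0.5)


def test_bedpe_roundtrip(tmp_path):
    loops = [loop(20_000, 80_000, "La"), loop(40_000, 400_000, "Lb", 1.5, 0.4)]
    p = tmp_path / "loops.bedpe"
    write_bedpe(loops, p)
    back = read_bedpe(p)
    assert back == loops


class TestAnnotateAnchor:
    def test_single_and_mixed_overlaps(self):
        enh = FeatureIndex([("E1", GenomicInterval("chr1", 19_500, 20_000))])
        prom = FeatureIndex([("P1", GenomicInterval("chr1", 20_500, 23_000))])
        a = anchor(20_000)
        assert annotate_anchor(a, enh, prom) == ({"E1"}, {"P1"})
        far = anchor(900_000)
        assert annotate_anchor(far, enh, prom) == (set(), set())

    def test_matches_all_pairs_brute_force(self):
        rng = np.random.default_rng(71)
        features = []
        for i in range(200):
            s = int(rng.integers(0, 1_000_000))
            features.append((f"F{i}", GenomicInterval("chr1", s, s + int(rng.integers(200, 3_000)))))
        index = FeatureIndex(features)
        for _ in range(200):
            a = anchor(int(rng.integers(2_000, 1_000_000)))
            got = index.query(a)
            expected = {
                fid
                for fid, iv in features
                if iv.start < a.end and a.start < iv.end
            }
            assert got == expected


class TestClassifyLoop:
    lp = loop(20_000, 80_000)

    def test_simple_ep(self):
        assert classify_loop(self.lp, ({"E1"}, set()), (set(), {"P1"})) == [
            ("EP", "E1", "P1")
        ]

    def test_inclusive_expansion_mixed(self):
        got = classify_loop(self.lp, ({"E1"}, {"P1"}), (set(), {"P2"}))
        assert set(got) == {("EP", "E1", "P2"), ("PP", "P1", "P2")}

    def test_cartesian_two_by_two(self):
        got = classify_loop(self.lp, ({"E1", "E2"}, set()), ({"E3"}, {"P1"}))
        assert len(got) == 4
        assert sum(1 for t, _, _ in got if t == "EE") == 2
        assert sum(1 for t, _, _ in got if t == "EP") == 2

    def test_unassigned_when_one_side_empty(self):
        assert classify_loop(self.lp, (set(), set()), ({"E1"}, set())) == [
            ("unassigned", None, None)
        ]

    def test_matches_cartesian_oracle_and_swap_symmetry(self):
        rng = np.random.default_rng(72)
        for _ in range(500):
            pool_e = [f"E{i}" for i in range(6)]
            pool_p = [f"P{i}" for i in range(6)]
            def draw():
                ne, np_ = int(rng.integers(0, 4)), int(rng.integers(0, 4))
                return (
                    set(rng.choice(pool_e, size=ne, replace=False)),
                    set(rng.choice(pool_p, size=np_, replace=False)),
                )
            ann1, ann2 = draw(), draw()
            got = classify_loop(self.lp, ann1, ann2)
            side1 = {("E", f) for f in ann1[0]} | {("P", f) for f in ann1[1]}
            side2 = {("E", f) for f in ann2[0]} | {("P", f) for f in ann2[1]}
            if not side1 or not side2:
                assert got == [("unassigned", None, None)]
                continue
            oracle = {frozenset((a, b)) for a in side1 for b in side2}
            assert {frozenset(((t[0], f1), (t[1], f2))) for t, f1, f2 in got} == oracle
            # anchor swap yields the same pair set
            swapped = classify_loop(self.lp, ann2, ann1)
            assert set(got) == set(swapped)


class TestPercentHalfUp:
    @pytest.mark.parametrize(
        "k,n,expected",
        [
            (889, 2868, 31),
            (180, 2606, 7),
            (30651, 44476, 69),
            (309, 330, 94),
            (238, 309, 77),
            (1, 8, 13),       # 12.5 rounds up
            (1, 200, 1),      # 0.5 rounds up
            (0, 10, 0),
        ],
    )
    def test_values(self, k, n, expected):
        assert percent_half_up(k, n) == expected

    def test_rejects_bad_input(self):
        with pytest.raises(ValueError):
            percent_half_up(1, 0)


def _records(enh, gene, enh_fdr=0.01, gene_fdr=0.01):
    return pd.DataFrame(
        {
            "enhancer_log2fc": enh,
            "gene_log2fc": gene,
            "enhancer_fdr": enh_fdr,
            "gene_fdr": gene_fdr,
        }
    )


class TestConcordanceSummary:
    def test_identical_dynamics_give_pearson_one(self):
        vals = [-2.0, -1.0, 0.5, 1.5]
        out = concordance_summary(_records(vals, vals))
        assert out["pearson"] == pytest.approx(1.0)
        assert out["spearman"] == pytest.approx(1.0)

    def test_category_counts_and_percentages(self):
        enh = [-2, -1, -3, 2, -1]
        gene = [-1, -2, 1, 1, -0.5]
        out = concordance_summary(_records(enh, gene))
        assert out["counts"]["enh_down_gene_down"] == 3
        assert out["percentages"]["enh_down_gene_down"] == 60
        assert out["counts"]["enh_up_gene_up"] == 1

    def test_degenerate_variance_is_undefined(self):
        out = concordance_summary(_records([1.0, 1.0, 1.0], [0.1, 0.2, 0.3]))
        assert out["pearson"] is None

    def test_too_few_records(self):
        with pytest.raises(ValueError):
            concordance_summary(_records([1.0], [1.0]))


class TestLoopDiffSummary:
    def test_printed_proportion(self):
        class L:
            log2fc = -1.0

        all_loops = [L()] * 44_476
        diff = [L()] * 30_651
        out = loop_diff_summary(all_loops, diff)
        assert out["percent"] == 69
        assert out["frac_negative"] == 1.0

    def test_none_differential(self):
        class L:
            log2fc = 0.0

        out = loop_diff_summary([L()] * 10, [])
        assert out["n_diff"] == 0 and out["percent"] == 0

    def test_matches_direct_division(self):
        rng = np.random.default_rng(81)

        class L:
            def __init__(self, v):
                self.log2fc = v

        for _ in range(50):
            n = int(rng.integers(1, 500))
            k = int(rng.integers(0, n + 1))
            diff = [L(float(rng.normal())) for _ in range(k)]
            out = loop_diff_summary([L(0.0)] * n, diff)
            assert out["percent"] == int(np.floor(100 * k / n + 0.5))

    def test_empty_total_is_error(self):
        with pytest.raises(ValueError):
            loop_diff_summary([], [])


class TestBuildMasterTable:
    def setup_method(self):
        self.enh = FeatureIndex([("E1", GenomicInterval("chr1", 19_750, 20_250))])
        self.prom = FeatureIndex([("P_G1", GenomicInterval("chr1", 78_000, 80_500))])
        self.enh_diff = pd.DataFrame(
            {"feature_id": ["E1"], "log2fc": [-2.0], "fdr": [0.001]}
        ).set_index("feature_id")
        self.expr_diff = pd.DataFrame(
            {"feature_id": ["P_G1"], "log2fc": [-1.5], "fdr": [0.02]}
        ).set_index("feature_id")
        self.patient_epi = pd.DataFrame(
            {"feature_id": ["E1"], "log2fc": [1.2], "fdr": [0.01]}
        ).set_index("feature_id")
        self.patient_expr = pd.DataFrame(
            {"feature_id": ["P_G1"], "log2fc": [-0.2], "fdr": [0.01]}
        ).set_index("feature_id")
        self.kwargs = dict(
            enhancers=self.enh,
            promoters=self.prom,
            enhancer_diff=self.enh_diff,
            expression_diff=self.expr_diff,
            p52_peaks=[GenomicInterval("chr1", 19_900, 20_100)],
            consensus_ses=[ConsensusSE(GenomicInterval("chr1", 15_000, 30_000), frozenset({"s"}))],
            stabilo_classes={"E1": "de_novo"},
            patient_epigenomic=self.patient_epi,
            patient_expression=self.patient_expr,
            essential_genes={"P_G1"},
        )

    def test_single_ep_loop_fully_joined(self):
        table = build_master_table([loop(20_000, 79_000)], **self.kwargs)
        assert len(table) == 1
        row = table.iloc[0]
        assert row["enhancer_id"] == "E1" and row["gene_id"] == "P_G1"
        assert row["enhancer_log2fc"] == -2.0
        assert row["gene_log2fc"] == -1.5
        assert bool(row["p52_bound"]) and bool(row["se_member"])
        assert row["stabilo_class"] == "de_novo"
        assert bool(row["nfkb_enriched_epigenome"])
        assert not bool(row["nfkb_enriched_expression"])  # negative log2fc
        assert bool(row["essential"])

    def test_repeated_ep_pair_keeps_per_loop_granularity(self):
        loops = [loop(20_000, 79_000, "L1"), loop(20_000, 79_000, "L2", log2fc=0.5)]
        table = build_master_table(loops, **self.kwargs)
        assert len(table) == 2
        assert set(table["loop_id"]) == {"L1", "L2"}

    def test_missing_diff_entry_recorded_not_dropped(self):
        kwargs = dict(self.kwargs, enhancer_diff=self.enh_diff.drop("E1"))
        table = build_master_table([loop(20_000, 79_000)], **kwargs)
        assert len(table) == 1
        assert np.isnan(table.iloc[0]["enhancer_log2fc"])

    def test_non_ep_loops_excluded(self):
        # both anchors on the promoter side -> PP only -> no master rows
        table = build_master_table([loop(79_000, 79_000 + 15_000)], **self.kwargs)
        assert table.empty
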