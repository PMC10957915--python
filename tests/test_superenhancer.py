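"""Super-enhancer calling: TSS exclusion, stitching, tangent cutoff,
cross-sample consensus."""

import numpy as np
import pytest

from mmreg.intervals import ConsensusPeak, GenomicInterval, Peak
from mmreg.superenhancer import (
    StitchedRegion,
    assign_constituents,
    consensus_se,
    exclude_tss_peaks,
    se_membership,
    stitch,
    tangent_cutoff,
)
from conftest import make_gene


def peak(start, end, signal=1.0, chrom="chr1"):
    return Peak(GenomicInterval(chrom, start, end), signal)


class TestExcludeTss:
    genes = [make_gene("G1", "chr1", 10_000, 13_000, "+")]  # TSS 10000

    def test_peak_in_window_removed(self):
        kept = exclude_tss_peaks([peak(9_000, 9_400)], self.genes)
        assert kept == []

    def test_distant_peak_kept(self):
        kept = exclude_tss_peaks([peak(1_010_000, 1_010_400)], self.genes)
        assert len(kept) == 1

    def test_matches_brute_force_window_filter(self):
        rng = np.random.default_rng(31)
        genes = [
            make_gene(f"G{i}", "chr1", int(s), int(s) + 3_000,
                      "+" if rng.random() < 0.5 else "-")
            for i, s in enumerate(rng.integers(10_000, 3_000_000, size=20))
        ]
        peaks = []
        for s in rng.integers(0, 3_000_000, size=200):
            peaks.append(peak(int(s), int(s) + int(rng.integers(200, 1_500))))
        kept = exclude_tss_peaks(peaks, genes)
        expected = []
        for p in peaks:
            hit = False
            for g in genes:
                lo, hi = g.tss - 2_500, g.tss + 2_500
                if p.interval.start < hi and lo < p.interval.end:
                    hit = True
                    break
            if not hit:
                expected.append(p)
        assert kept == expected


class TestStitch:
    def test_gap_within_distance_merges(self):
        regions = stitch([peak(0, 500), peak(12_000, 12_500)])
        assert len(regions) == 1
        assert regions[0].interval == GenomicInterval("chr1", 0, 12_500)

    def test_gap_beyond_distance_stays_split(self):
        regions = stitch([peak(0, 500), peak(13_100, 13_600)])
        assert len(regions) == 2

    def test_signal_is_sum_of_constituents(self):
        regions = stitch([peak(0, 500, 2.0), peak(1_000, 1_500, 3.5)])
        assert regions[0].signal == pytest.approx(5.5)
        assert len(regions[0].constituent_peaks) == 2

    @staticmethod
    def _union_find_oracle(peaks, d):
        # transitive closure over pairs with edge-to-edge gap <= d
        n = len(peaks)
        parent = list(range(n))

        def find(i):
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for i in range(n):
            for j in range(i + 1, n):
                a, b = peaks[i].interval, peaks[j].interval
                if a.chrom != b.chrom:
                    continue
                gap = max(a.start, b.start) - min(a.end, b.end)
                if gap <= d:
                    parent[find(i)] = find(j)
        clusters = {}
        for i in range(n):
            clusters.setdefault(find(i), []).append(peaks[i])
        out = []
        for members in clusters.values():
            out.append(
                (
                    members[0].interval.chrom,
                    min(p.interval.start for p in members),
                    max(p.interval.end for p in members),
                    sum(p.signal for p in members),
                )
            )
        return sorted(out)

    def test_matches_union_find_oracle_on_random_sets(self):
        rng = np.random.default_rng(41)
        for trial in range(100):
            d = int(rng.choice([500, 5_000, 12_500]))
            peaks = []
            for _ in range(int(rng.integers(2, 50))):
                chrom = f"chr{int(rng.integers(1, 3))}"
                s = int(rng.integers(0, 300_000))
                peaks.append(
                    peak(s, s + int(rng.integers(100, 2_000)),
                         float(rng.uniform(0, 10)), chrom)
                )
            got = sorted(
                (r.interval.chrom, r.interval.start, r.interval.end, r.signal)
                for r in stitch(peaks, d)
            )
            expected = self._union_find_oracle(peaks, d)
            assert [g[:3] for g in got] == [e[:3] for e in expected]
            assert np.allclose([g[3] for g in got], [e[3] for e in expected])

    def test_idempotent(self):
        rng = np.random.default_rng(43)
        peaks = [
            peak(int(s), int(s) + 300, 1.0)
            for s in rng.integers(0, 500_000, size=40)
        ]
        once = stitch(peaks)
        as_peaks = [Peak(r.interval, r.signal) for r in once]
        twice = stitch(as_peaks)
        assert [r.interval for r in once] == [r.interval for r in twice]


def regions_from_signals(signals):
    return [
        StitchedRegion(GenomicInterval("chr1", 1_000 * i, 1_000 * i + 500), (), float(s))
        for i, s in enumerate(signals)
    ]


def oracle_super_flags(signals):
    """Geometric oracle: chord through (1, y_1) and (n, y_n); the tangent
    point maximises the vertical drop below the chord (largest index on
    ties); super = strictly above the cutoff signal."""
    ys = sorted(signals)
    n = len(ys)
    if ys[0] == ys[-1]:
        return [False] * n
    span = ys[-1] - ys[0]
    # vertical drop below the chord through (0, y_0) and (n-1, y_{n-1}),
    # scaled by (n-1) so endpoint ties are exact in floating point
    drops = [span * i - (ys[i] - ys[0]) * (n - 1) for i in range(n)]
    best = max(range(n), key=lambda i: (drops[i], i))
    cutoff = ys[best]
    return [sig > cutoff for sig in signals]


class TestTangentCutoff:
    def test_hockey_stick(self):
        regions = tangent_cutoff(regions_from_signals([1, 1, 1, 1, 100]))
        assert [r.is_super for r in regions] == [False, False, False, False, True]
        assert regions[-1].rank == 1

    def test_linear_signals_have_no_supers(self):
        regions = tangent_cutoff(regions_from_signals(list(range(1, 21))))
        assert not any(r.is_super for r in regions)

    def test_affine_invariance(self):
        rng = np.random.default_rng(51)
        for _ in range(100):
            signals = rng.uniform(0, 100, size=int(rng.integers(3, 40)))
            base = [r.is_super for r in tangent_cutoff(regions_from_signals(signals))]
            a, b = float(rng.uniform(0.1, 9)), float(rng.uniform(-50, 50))
            scaled = [r.is_super for r in tangent_cutoff(regions_from_signals(a * signals + b))]
            assert base == scaled

    def test_matches_geometric_oracle(self):
        rng = np.random.default_rng(52)
        for _ in range(100):
            n = int(rng.integers(3, 60))
            signals = list(np.round(rng.uniform(0, 50, size=n), 3))
            if rng.random() < 0.3:  # inject hockey sticks
                signals[-1] *= 50
            got = [r.is_super for r in tangent_cutoff(regions_from_signals(signals))]
            assert got == oracle_super_flags(signals)

    def test_super_count_bound(self):
        rng = np.random.default_rng(53)
        for _ in range(50):
            signals = rng.uniform(0, 10, size=int(rng.integers(3, 30)))
            regions = tangent_cutoff(regions_from_signals(signals))
            assert sum(r.is_super for r in regions) <= len(regions) - 1

    def test_identical_signals_flag_nothing(self):
        regions = tangent_cutoff(regions_from_signals([5, 5, 5, 5]))
        assert not any(r.is_super for r in regions)

    def test_too_few_regions(self):
        with pytest.raises(ValueError):
            tangent_cutoff(regions_from_signals([1, 2]))

    def test_ranks_descend_by_signal(self):
        regions = tangent_cutoff(regions_from_signals([3, 9, 1, 9]))
        by_rank = sorted(regions, key=lambda r: r.rank)
        assert [r.signal for r in by_rank] == [9, 9, 3, 1]
        # tie broken by leftmost coordinate
        assert by_rank[0].interval.start < by_rank[1].interval.start


def region(start, end, chrom="chr1"):
    return GenomicInterval(chrom, start, end)


class TestConsensusSE:
    def test_identical_se_in_two_samples(self):
        out = consensus_se({"a": [region(0, 10_000)], "b": [region(0, 10_000)]})
        assert len(out) == 1
        assert out[0].member_samples == frozenset({"a", "b"})

    def test_forty_percent_overlap_is_not_membership(self):
        # the rule is measured as a fraction of the ORIGINAL sample SE
        original = region(0, 10_000)
        assert not se_membership(original, region(6_000, 20_000))  # 40%
        assert se_membership(original, region(5_000, 20_000))  # 50%, inclusive

    def test_union_merge_keeps_contributors_as_members(self):
        out = consensus_se({"a": [region(0, 10_000)], "b": [region(6_000, 16_000)]})
        assert len(out) == 1
        assert out[0].member_samples == frozenset({"a", "b"})

    def test_matches_brute_force_membership(self):
        rng = np.random.default_rng(61)
        for _ in range(30):
            per_sample = {}
            for s in ("s1", "s2", "s3"):
                ses = []
                for _ in range(int(rng.integers(1, 6))):
                    start = int(rng.integers(0, 200_000))
                    ses.append(region(start, start + int(rng.integers(2_000, 30_000))))
                per_sample[s] = ses
            out = consensus_se(per_sample)
            # brute force: merged regions, membership by >=50% of original SE
            from mmreg.intervals import merge_intervals

            merged = merge_intervals([iv for ses in per_sample.values() for iv in ses])
            assert [c.interval for c in out] == merged
            for c in out:
                expected = {
                    s
                    for s, ses in per_sample.items()
                    if any(iv.overlap_bp(c.interval) / iv.width >= 0.5 for iv in ses)
                }
                assert c.member_samples == frozenset(expected)


class TestAssignConstituents:
    def cp(self, start):
        return ConsensusPeak(GenomicInterval("chr1", start, start + 500), 2)

    def test_midpoint_rule(self):
        from mmreg.superenhancer import ConsensusSE

        se = ConsensusSE(region(1_000, 5_000), frozenset({"a"}))
        inside = self.cp(2_000)          # midpoint 2250 inside
        outside = self.cp(100_000)       # far away
        edge = self.cp(4_800)            # overlaps edge, midpoint 5050 outside
        out = assign_constituents([se], [inside, outside, edge])
        assert out[0].constituent_consensus_peaks == (inside,)
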