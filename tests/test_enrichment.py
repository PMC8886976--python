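import numpy as np
import pytest
from scipy import stats

from tadcnv import enrichment as enr
from tadcnv.enrichment import Isochore
from tadcnv.variants_io import GenomicInterval as GI


def uniform_isochores(length=100_000, chrom="chr1", gc_class=0):
    return [Isochore(GI(chrom, 0, length), gc_class)]


class TestBuildIsochores:
    def test_uniform_gc_one_isochore_per_chromosome(self):
        ws = [GI("chr1", 0, 3000), GI("chr2", 0, 2000)]
        track = [("chr1", 0, 1000, 0.4), ("chr1", 1000, 2000, 0.4), ("chr1", 2000, 3000, 0.4),
                 ("chr2", 0, 1000, 0.4), ("chr2", 1000, 2000, 0.4)]
        iso = enr.build_isochores(ws, track, n_gc_classes=4)
        assert len(iso) == 2
        assert iso[0].interval == GI("chr1", 0, 3000)

    def test_alternating_classes_no_merging(self):
        ws = [GI("chr1", 0, 4000)]
        track = [("chr1", i * 1000, (i + 1) * 1000, 0.3 if i % 2 == 0 else 0.7) for i in range(4)]
        iso = enr.build_isochores(ws, track, n_gc_classes=2)
        assert len(iso) == 4

    def test_binning_then_run_length_merge(self):
        # classes on [0,1] with 2 bins: 0.3 -> 0, 0.31 -> 0, 0.6 -> 1
        ws = [GI("chr1", 0, 3000)]
        track = [("chr1", 0, 1000, 0.3), ("chr1", 1000, 2000, 0.31), ("chr1", 2000, 3000, 0.6)]
        iso = enr.build_isochores(ws, track, n_gc_classes=2)
        assert [(i.interval.start, i.interval.end, i.gc_class) for i in iso] == [
            (0, 2000, 0), (2000, 3000, 1)
        ]

    def test_window_outside_workspace_rejected(self):
        with pytest.raises(ValueError, match="outside workspace"):
            enr.build_isochores([GI("chr1", 0, 1000)], [("chr1", 500, 1500, 0.4)], 2)


class TestSampleSegments:
    def test_forced_placement_when_isochore_equals_segment(self):
        iso = [Isochore(GI("chr1", 100, 200), 0)]
        seg = [GI("chr1", 100, 200)]
        for seed in range(5):
            assert enr.sample_segments(seg, iso, seed=seed) == seg

    def test_length_multiset_conserved(self, rng):
        iso = uniform_isochores()
        segs = []
        for _ in range(30):
            l = int(rng.integers(10, 2000))
            s = int(rng.integers(0, 100_000 - l))
            segs.append(GI("chr1", s, s + l))
        placed = enr.sample_segments(segs, iso, seed=3)
        assert sorted(p.length for p in placed) == sorted(s.length for s in segs)

    def test_start_positions_uniform_chi_square(self):
        # one uniform-GC chromosome of length L, one segment of length l:
        # starts over many samples are uniform on [0, L - l]
        L, l = 10_000, 100
        iso = [Isochore(GI("chr1", 0, L), 0)]
        seg = [GI("chr1", 0, l)]
        rng_draws = []
        sampler = enr._SegmentSampler(seg, iso)
        rng = np.random.default_rng(0)
        for _ in range(10_000):
            rng_draws.append(sampler.sample(rng)[0].start)
        counts, _ = np.histogram(rng_draws, bins=20, range=(0, L - l + 1))
        p = stats.chisquare(counts).pvalue
        assert p > 0.001

    def test_gc_class_preserved(self, blocky_genome):
        iso = enr.build_isochores(
            blocky_genome.workspace, blocky_genome.gc_track, n_gc_classes=4
        )
        class_by_pos = sorted(iso, key=lambda i: (i.interval.chrom, i.interval.start))

        def class_of(seg):
            best, best_ov = None, 0
            for i in class_by_pos:
                ov = i.interval.overlap_len(seg)
                if ov > best_ov:
                    best, best_ov = i.gc_class, ov
            return best

        segs = [GI("chr1", s, s + 5_000) for s in range(0, 500_000, 50_000)]
        placed = enr.sample_segments(segs, iso, seed=1)
        for orig, new in zip(segs, placed):
            assert class_of(new) == class_of(orig)

    def test_oversized_segment_falls_back_with_warning(self):
        iso = [Isochore(GI("chr1", 0, 100), 0), Isochore(GI("chr1", 100, 10_000), 1)]
        # [0,150) is mostly class 0 (100 bp vs 50 bp) but longer than the only
        # class-0 isochore -> workspace-wide fallback
        big = [GI("chr1", 0, 150)]
        with pytest.warns(UserWarning, match="placed anywhere"):
            placed = enr.sample_segments(big, iso, seed=0)
        assert placed[0].length == 150


class TestSegmentOverlapCount:
    def test_empty_annotation(self):
        assert enr.segment_overlap_count([GI("chr1", 0, 100)], []) == 0

    def test_two_of_three(self):
        segs = [GI("chr1", 0, 100), GI("chr1", 500, 600), GI("chr1", 5000, 5100)]
        ann = [GI("chr1", 50, 550)]
        assert enr.segment_overlap_count(segs, ann) == 2

    def test_segment_spanning_two_annotations_counts_once(self):
        segs = [GI("chr1", 0, 1000)]
        ann = [GI("chr1", 10, 20), GI("chr1", 500, 600)]
        assert enr.segment_overlap_count(segs, ann) == 1

    def test_brute_force_equivalence(self, rng):
        for _ in range(100):
            segs, ann = [], []
            for _ in range(int(rng.integers(1, 20))):
                s = int(rng.integers(0, 9_000))
                segs.append(GI("chr1", s, s + int(rng.integers(1, 500))))
            for _ in range(int(rng.integers(0, 20))):
                s = int(rng.integers(0, 9_000))
                ann.append(GI("chr2" if rng.random() < 0.2 else "chr1", s, s + int(rng.integers(1, 500))))
            oracle = sum(1 for s in segs if any(s.overlaps(a) for a in ann))
            assert enr.segment_overlap_count(segs, ann) == oracle


class TestEnrichmentTest:
    def test_saturating_annotation(self):
        iso = uniform_isochores(10_000)
        segs = [GI("chr1", 100, 200), GI("chr1", 5_000, 5_050)]
        res = enr.enrichment_test(segs, [GI("chr1", 0, 10_000)], iso, n_samples=50, seed=0)
        assert res.observed == res.expected == len(segs)
        assert res.log2_fc == 0.0 and res.p_value == 1.0

    def test_pseudocount_minimum_p(self):
        # annotation hit by the observed segment but unreachable by any of the
        # 99 random placements under this seed -> p = (0+1)/(99+1)
        iso = uniform_isochores(1_000_000)
        segs = [GI("chr1", 0, 10)]
        ann = [GI("chr1", 0, 10)]
        res = enr.enrichment_test(segs, ann, iso, n_samples=99, seed=0)
        assert res.observed == 1
        assert res.p_value == pytest.approx((0 + 1) / (99 + 1)) == pytest.approx(0.01)
        assert res.direction == "enriched"

    def test_log2_fold_change_arithmetic(self):
        # observed 8, expected 4 -> log2 FC = 1
        assert np.log2(8 / 4) == 1.0  # arithmetic anchor for the field formula

    def test_merges_query_segments_first(self):
        iso = uniform_isochores(10_000)
        # two overlapping segments merge into one -> observed counts once
        segs = [GI("chr1", 100, 300), GI("chr1", 200, 400)]
        res = enr.enrichment_test(segs, [GI("chr1", 0, 10_000)], iso, n_samples=20, seed=0)
        assert res.observed == 1

    def test_infinite_fc_flag(self):
        # annotation on a chromosome the sampler cannot reach -> expected 0
        iso = uniform_isochores(10_000)
        segs = [GI("chr1", 0, 10)]
        res = enr.enrichment_test(segs, [GI("chr2", 0, 10_000)], iso, n_samples=20, seed=0)
        assert res.observed == 0 and res.expected == 0 and res.log2_fc == 0.0

    def test_seed_reproducibility(self, rng):
        iso = uniform_isochores()
        segs = [GI("chr1", int(s), int(s) + 500) for s in rng.integers(0, 90_000, 10)]
        ann = [GI("chr1", int(s), int(s) + 800) for s in rng.integers(0, 90_000, 15)]
        r1 = enr.enrichment_test(segs, ann, iso, n_samples=100, seed=5)
        r2 = enr.enrichment_test(segs, ann, iso, n_samples=100, seed=5)
        assert (r1.expected, r1.p_value) == (r2.expected, r2.p_value)


class TestCorrectPvalues:
    def test_single_p_unchanged(self):
        assert enr.correct_pvalues([0.03])[0] == pytest.approx(0.03)

    def test_bh_arithmetic(self):
        # p(i) * m / i then cumulative min from the top: all 0.04
        q = enr.correct_pvalues([0.01, 0.02, 0.03, 0.04])
        np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_all_equal(self):
        q = enr.correct_pvalues([0.2, 0.2, 0.2])
        np.testing.assert_allclose(q, 0.2)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            enr.correct_pvalues([0.5, 0.0])
        with pytest.raises(ValueError):
            enr.correct_pvalues([1.5])

    def test_q_at_least_p_after_bh(self, rng):
        p = rng.uniform(0.001, 1, size=20)
        q = enr.correct_pvalues(p)
        assert np.all(q >= p - 1e-12)


class TestCompareFoldChanges:
    @staticmethod
    def result(name, log2_fc, q):
        return enr.EnrichmentResult(name, 8, 4, log2_fc, 0.01, q, 100, "enriched")

    def test_identical_results_zero_difference(self):
        a = [self.result("genes", 0.5, 0.005)]
        out = enr.compare_fold_changes(a, a)
        assert out["log2_fc_diff"].tolist() == [0.0]

    def test_difference_arithmetic(self):
        a = [self.result("genes", 0.5, 0.005)]
        b = [self.result("genes", -0.3, 0.005)]
        out = enr.compare_fold_changes(a, b)
        assert out["log2_fc_diff"][0] == pytest.approx(0.8)
        assert bool(out["both_significant"][0])

    def test_one_side_nonsignificant_flagged(self):
        a = [self.result("genes", 0.5, 0.5)]
        b = [self.result("genes", 0.2, 0.001)]
        out = enr.compare_fold_changes(a, b, q_threshold=0.01)
        assert not bool(out["both_significant"][0])

    def test_mismatched_annotations_listed(self):
        a = [self.result("genes", 0.5, 0.005)]
        b = [self.result("enhancers", 0.5, 0.005)]
        with pytest.raises(ValueError, match="enhancers"):
            enr.compare_fold_changes(a, b)
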