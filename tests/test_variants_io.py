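import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tadcnv import variants_io as vio
from tadcnv.variants_io import CNV, GenomicInterval, ParseError


def make_cnv(chrom, start, end, svtype="DEL", label="unknown", af=None, source="", id=None):
    return CNV(
        GenomicInterval(chrom, start, end), svtype, label, af, source,
        id or f"{chrom}:{start}-{end}",
    )


class TestGenomicInterval:
    def test_length(self):
        assert GenomicInterval("chr1", 100, 250).length == 150

    @pytest.mark.parametrize("start,end", [(-1, 10), (10, 10), (10, 5)])
    def test_invalid_coordinates_rejected(self, start, end):
        with pytest.raises(ValueError):
            GenomicInterval("chr1", start, end)

    def test_distance_overlap_is_zero(self):
        a, b = GenomicInterval("chr1", 0, 100), GenomicInterval("chr1", 50, 150)
        assert a.distance_to(b) == 0

    def test_distance_gap(self):
        a, b = GenomicInterval("chr1", 0, 100), GenomicInterval("chr1", 300, 400)
        assert a.distance_to(b) == 200
        assert b.distance_to(a) == 200


class TestReadCnvs:
    def test_bed_line_round_trip(self, tmp_path):
        p = tmp_path / "c.bed"
        p.write_text("chr1\t1000\t2000\tDEL\n")
        (c,) = vio.read_cnvs(p, "BED")
        assert (c.chrom, c.interval.start, c.interval.end, c.svtype) == ("chr1", 1000, 2000, "DEL")

    def test_empty_file_gives_empty_set(self, tmp_path):
        p = tmp_path / "empty.bed"
        p.write_text("")
        assert vio.read_cnvs(p, "BED") == []

    def test_malformed_line_names_line_number(self, tmp_path):
        p = tmp_path / "bad.bed"
        p.write_text("chr1\t0\t100\tDEL\nchr1\tfoo\tbar\tDUP\n")
        with pytest.raises(ParseError, match="line 2"):
            vio.read_cnvs(p, "BED")

    def test_unsupported_svtype_skipped_with_warning(self, tmp_path):
        p = tmp_path / "inv.bed"
        p.write_text("chr1\t0\t100\tINV\nchr1\t0\t100\tDEL\n")
        with pytest.warns(UserWarning, match="skipped 1"):
            cnvs = vio.read_cnvs(p, "BED")
        assert len(cnvs) == 1

    def test_vcf_one_based_conversion(self, tmp_path):
        # 1-based inclusive [1001, 2000] covers 1000 bases -> half-open [1000, 2000)
        p = tmp_path / "c.vcf"
        vio.write_cnvs_vcf(
            [make_cnv("chr1", 1000, 2000, "DEL", id="v1")], p, {"chr1": 10_000}
        )
        assert "\t1001\t" in p.read_text()
        (c,) = vio.read_cnvs(p, "VCF")
        assert (c.interval.start, c.interval.end) == (1000, 2000)
        assert c.interval.length == 1000

    def test_vcf_af_round_trip(self, tmp_path):
        p = tmp_path / "c.vcf"
        vio.write_cnvs_vcf([make_cnv("chr1", 10, 500, "DUP", af=0.25)], p, {"chr1": 10_000})
        (c,) = vio.read_cnvs(p, "VCF")
        assert c.af == pytest.approx(0.25)


class TestFilterCnvs:
    def test_size_boundary_is_strict(self):
        # "larger than 50 bp" removes a variant of length exactly 50
        exact = make_cnv("chr1", 0, 50)
        bigger = make_cnv("chr1", 0, 51)
        assert vio.filter_cnvs([exact, bigger], min_size_bp=50) == [bigger]

    def test_autosomes_only(self):
        kept = vio.filter_cnvs(
            [make_cnv("chrX", 0, 1000), make_cnv("chr5", 0, 1000)], autosomes_only=True
        )
        assert [c.chrom for c in kept] == ["chr5"]

    def test_identity_when_all_pass(self):
        cnvs = [make_cnv("chr1", i * 1000, i * 1000 + 600) for i in range(10)]
        assert vio.filter_cnvs(cnvs, min_size_bp=50) == cnvs

    def test_af_boundary_modes(self):
        c = make_cnv("chr1", 0, 1000, af=0.1)
        assert vio.filter_cnvs([c], af_max=0.1, af_strict=True) == []
        assert vio.filter_cnvs([c], af_max=0.1, af_strict=False) == [c]

    def test_idempotent(self, labeled_cnvs):
        once = vio.filter_cnvs(labeled_cnvs, min_size_bp=50, autosomes_only=True)
        assert vio.filter_cnvs(once, min_size_bp=50, autosomes_only=True) == once


class TestReciprocalOverlap:
    def test_identity(self):
        a = GenomicInterval("chr1", 100, 200)
        assert vio.reciprocal_overlap(a, a) == 1.0

    def test_disjoint(self):
        assert vio.reciprocal_overlap(
            GenomicInterval("chr1", 0, 100), GenomicInterval("chr1", 200, 300)
        ) == 0.0

    def test_half_overlap(self):
        # per-base count: [0,100) and [50,150) share bases 50..99 -> 50/100 each
        assert vio.reciprocal_overlap(
            GenomicInterval("chr1", 0, 100), GenomicInterval("chr1", 50, 150)
        ) == pytest.approx(0.5)

    def test_different_chromosomes(self):
        assert vio.reciprocal_overlap(
            GenomicInterval("chr1", 0, 100), GenomicInterval("chr2", 0, 100)
        ) == 0.0

    @given(
        s1=st.integers(0, 500), l1=st.integers(1, 200),
        s2=st.integers(0, 500), l2=st.integers(1, 200),
    )
    @settings(max_examples=200, deadline=None)
    def test_matches_per_base_oracle_and_is_symmetric(self, s1, l1, s2, l2):
        a = GenomicInterval("chr1", s1, s1 + l1)
        b = GenomicInterval("chr1", s2, s2 + l2)
        shared = len(set(range(s1, s1 + l1)) & set(range(s2, s2 + l2)))
        oracle = min(shared / l1, shared / l2)
        got = vio.reciprocal_overlap(a, b)
        assert got == pytest.approx(oracle)
        assert got == pytest.approx(vio.reciprocal_overlap(b, a))
        assert 0.0 <= got <= 1.0
        assert (got == 1.0) == (a == b)


class TestClusterAndDeduplicate:
    def test_smallest_kept(self):
        a = make_cnv("chr1", 0, 1000, id="A")
        b = make_cnv("chr1", 0, 990, id="B")
        assert vio.reciprocal_overlap(a.interval, b.interval) == pytest.approx(0.99)
        kept = vio.cluster_and_deduplicate([a, b], threshold=0.9, tie_rule="smallest")
        assert kept == [b]

    def test_disjoint_pair_both_kept(self):
        a, b = make_cnv("chr1", 0, 100, id="A"), make_cnv("chr1", 500, 600, id="B")
        assert len(vio.cluster_and_deduplicate([a, b], threshold=0.9)) == 2

    def test_source_priority(self):
        priority = ["audano2019", "gnomad_sv", "dgv", "ukbiobank"]
        a = make_cnv("chr1", 0, 1000, source="dgv", id="dgv1")
        b = make_cnv("chr1", 5, 1000, source="audano2019", id="aud1")
        kept = vio.cluster_and_deduplicate(
            [a, b], threshold=0.9, tie_rule="source_priority", priority=priority
        )
        assert kept == [b]

    def test_unknown_source_warns_and_sorts_last(self):
        a = make_cnv("chr1", 0, 1000, source="mystery", id="m1")
        b = make_cnv("chr1", 5, 1000, source="dgv", id="d1")
        with pytest.warns(UserWarning, match="mystery"):
            kept = vio.cluster_and_deduplicate(
                [a, b], threshold=0.9, tie_rule="source_priority", priority=["dgv"]
            )
        assert kept == [b]

    def test_transitive_closure_single_linkage(self):
        # A~B and B~C at >= 0.9 but A~C below threshold: all one cluster
        a = make_cnv("chr1", 0, 1000, id="A")
        b = make_cnv("chr1", 60, 1010, id="B")
        c = make_cnv("chr1", 120, 1030, id="C")
        assert vio.reciprocal_overlap(a.interval, c.interval) < 0.9
        assert vio.reciprocal_overlap(a.interval, b.interval) >= 0.9
        assert vio.reciprocal_overlap(b.interval, c.interval) >= 0.9
        kept = vio.cluster_and_deduplicate([a, b, c], threshold=0.9)
        assert len(kept) == 1

    def test_no_remaining_pair_above_threshold(self, rng):
        cnvs = []
        for i in range(200):
            start = int(rng.integers(0, 5_000))
            length = int(rng.integers(50, 400))
            cnvs.append(make_cnv("chr1", start, start + length, id=f"v{i}"))
        kept = vio.cluster_and_deduplicate(cnvs, threshold=0.9, tie_rule="smallest")
        assert set(c.id for c in kept) <= set(c.id for c in cnvs)
        for i, a in enumerate(kept):
            for b in kept[i + 1 :]:
                assert vio.reciprocal_overlap(a.interval, b.interval) < 0.9

    def test_svtypes_not_merged(self):
        a = make_cnv("chr1", 0, 1000, svtype="DEL", id="A")
        b = make_cnv("chr1", 0, 1000, svtype="DUP", id="B")
        assert len(vio.cluster_and_deduplicate([a, b], threshold=0.9)) == 2


class TestEcdfSizeBins:
    def test_degenerate_all_equal(self):
        binning = vio.ecdf_size_bins([100] * 50, n_bins=60)
        assert binning.n_bins == 1
        assert set(binning.assign([100] * 50)) == {0}

    def test_uniform_1_to_120_two_per_bin(self):
        binning = vio.ecdf_size_bins(list(range(1, 121)), n_bins=60)
        counts = np.bincount(binning.assign(list(range(1, 121))), minlength=binning.n_bins)
        assert binning.n_bins == 60
        assert np.all(counts == 2)

    def test_single_bin_spans_min_max(self):
        binning = vio.ecdf_size_bins([5, 9, 100], n_bins=1)
        assert binning.edges == (5.0, 100.0)

    def test_every_size_in_exactly_one_bin(self, rng):
        sizes = rng.integers(50, 10_000, size=500)
        binning = vio.ecdf_size_bins(sizes, n_bins=60)
        idx = binning.assign(sizes)
        assert np.all((idx >= 0) & (idx < binning.n_bins))

    def test_invalid_n_bins(self):
        with pytest.raises(ValueError):
            vio.ecdf_size_bins([1, 2, 3], n_bins=0)


class TestSizeMatch:
    @staticmethod
    def _cnvs(sizes, label, prefix):
        return [
            CNV(GenomicInterval("chr1", 0, s), "DEL", label, None, "", f"{prefix}{i}")
            for i, s in enumerate(sizes)
        ]

    def test_identical_multisets_fully_retained(self):
        sizes = [100, 200, 300, 400, 500] * 4
        p = self._cnvs(sizes, "pathogenic", "P")
        n = self._cnvs(sizes, "nonpathogenic", "N")
        mp, mn = vio.size_match(p, n, n_bins=5, seed=0)
        assert len(mp) == len(p) and len(mn) == len(n)

    def test_per_bin_min_count(self):
        # one effective bin: 5 pathogenic, 2 non-pathogenic -> 2 of each
        p = self._cnvs([100, 110, 120, 130, 140], "pathogenic", "P")
        n = self._cnvs([105, 115], "nonpathogenic", "N")
        mp, mn = vio.size_match(p, n, n_bins=1, seed=0)
        assert len(mp) == len(mn) == 2

    def test_balanced_and_without_replacement(self, rng):
        p = self._cnvs(rng.integers(60, 5_000, size=200), "pathogenic", "P")
        n = self._cnvs(rng.integers(100, 20_000, size=300), "nonpathogenic", "N")
        mp, mn = vio.size_match(p, n, n_bins=10, seed=3)
        assert len(mp) == len(mn)
        assert len({c.id for c in mp}) == len(mp)
        assert len({c.id for c in mn}) == len(mn)
        assert {c.id for c in mp} <= {c.id for c in p}
        assert {c.id for c in mn} <= {c.id for c in n}

    def test_seed_reproducibility(self, rng):
        p = self._cnvs(rng.integers(60, 5_000, size=100), "pathogenic", "P")
        n = self._cnvs(rng.integers(60, 5_000, size=100), "nonpathogenic", "N")
        r1 = vio.size_match(p, n, seed=42)
        r2 = vio.size_match(p, n, seed=42)
        assert [c.id for c in r1[0]] == [c.id for c in r2[0]]
        assert [c.id for c in r1[1]] == [c.id for c in r2[1]]
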