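"""Metagene profiles, region RPKM and exon-context comparisons."""

import numpy as np
import pytest

from clipscape.annotation import GenomeAnnotation, GenomicInterval, Transcript
from clipscape.clusters import window_counts
from clipscape.metagene import (
    AnchorSet,
    anchor_profile,
    compare_exon_context,
    coverage_ratio_profile,
    region_rpkm,
)
from clipscape.stats import mannwhitney_u

from .oracles import brute_region_count

SIZES = {"chr1": 2000}


def _uniform_bam(bam_builder, start=400, n=20, name="u.bam"):
    reads = [(f"r{i}", "chr1", start, "100M", "+") for i in range(n)]
    return bam_builder(reads, SIZES, name=name)


class TestAnchorProfile:
    def test_flat_coverage_flat_profile(self, bam_builder):
        bam = _uniform_bam(bam_builder)
        anchors = AnchorSet("a", [("chr1", 450, "+")])
        prof = anchor_profile([bam], anchors, SIZES, half_window=20, normalize="none")
        assert np.all(prof.values == prof.values[0]) and prof.values[0] == 20

    def test_minus_strand_orientation_flip(self, bam_builder):
        # coverage step: bases >= 500 covered, below not
        bam = bam_builder(
            [(f"r{i}", "chr1", 500, "100M", "+") for i in range(5)], SIZES
        )
        plus = anchor_profile(
            [bam], AnchorSet("p", [("chr1", 500, "+")]), SIZES, 30, "none"
        )
        minus = anchor_profile(
            [bam], AnchorSet("m", [("chr1", 500, "-")]), SIZES, 30, "none"
        )
        # + anchor: coverage at non-negative offsets; - anchor: mirrored
        assert plus.values[35] == 5 and plus.values[25] == 0
        assert np.array_equal(minus.values, plus.values[::-1])

    def test_cpm_invariant_under_duplication(self, bam_builder):
        bam1 = _uniform_bam(bam_builder, n=10, name="x.bam")
        bam2 = _uniform_bam(bam_builder, n=20, name="y.bam")  # doubled library
        anchors = AnchorSet("a", [("chr1", 450, "+")])
        p1 = anchor_profile([bam1], anchors, SIZES, 20, "cpm")
        p2 = anchor_profile([bam2], anchors, SIZES, 20, "cpm")
        assert np.allclose(p1.values, p2.values)

    def test_edge_truncated_anchor(self, bam_builder):
        bam = _uniform_bam(bam_builder, start=0, n=4)
        prof = anchor_profile(
            [bam], AnchorSet("a", [("chr1", 5, "+")]), SIZES, 20, "none"
        )
        assert prof.n_per_offset[0] == 0  # offset -20 undefined
        assert prof.n_per_offset[-1] == 1

    def test_empty_anchor_set_rejected(self, bam_builder):
        bam = _uniform_bam(bam_builder)
        with pytest.raises(ValueError):
            anchor_profile([bam], AnchorSet("a", []), SIZES, 20)

    def test_planted_peak_upstream_of_polya(self, small_bundle):
        """The exonic clusters sit ~100 nt upstream of poly(A) sites, so
        the CLIP metagene peaks in [-150, -50]."""
        _, ref, exp, outdir = small_bundle
        anchors = AnchorSet.from_bed(outdir / "polya.bed")
        prof = anchor_profile(
            exp.clip_bams, anchors, ref.ann.chrom_sizes, 300, "cpm"
        )
        assert -150 <= prof.argmax_offset <= -50


class TestCoverageRatio:
    def test_identity(self, bam_builder):
        bam = _uniform_bam(bam_builder)
        anchors = AnchorSet("a", [("chr1", 450, "+")])
        ratio, log2r = coverage_ratio_profile(bam, bam, anchors, SIZES, 20)
        assert np.allclose(ratio.values, 1.0)
        assert np.allclose(log2r.values, 0.0)

    def test_downstream_doubling(self, bam_builder):
        a = bam_builder(
            [(f"r{i}", "chr1", 500, "100M", "+") for i in range(40)]
            + [(f"l{i}", "chr1", 400, "100M", "+") for i in range(20)],
            SIZES, name="a.bam",
        )
        b = bam_builder(
            [(f"r{i}", "chr1", 500, "100M", "+") for i in range(20)]
            + [(f"l{i}", "chr1", 400, "100M", "+") for i in range(20)],
            SIZES, name="b.bam",
        )
        anchors = AnchorSet("a", [("chr1", 500, "+")])
        ratio, _ = coverage_ratio_profile(a, b, anchors, SIZES, 50)
        # library sizes differ (60 vs 40): cpm scaling makes the upstream
        # ratio < 1 and the downstream ratio ~ 2x upstream
        up = ratio.values[:40].mean()
        down = ratio.values[60:].mean()
        assert down / up == pytest.approx(2.0, rel=0.05)


class TestRegionRpkm:
    def test_consistent_with_window_counts(self, small_bundle):
        _, ref, exp, _ = small_bundle
        bam = exp.clip_bams[0]
        wc = window_counts(bam, ref.ann.chrom_sizes, 50)
        region = GenomicInterval("chr1", 1000, 1050)
        val = region_rpkm(bam, [region])[0]
        expected = wc.counts["chr1"][20] * 1e9 / (50 * wc.library_size)
        assert val == pytest.approx(expected)

    def test_length_scaling(self, bam_builder):
        bam = _uniform_bam(bam_builder)
        r1 = region_rpkm(bam, [GenomicInterval("chr1", 400, 500)])[0]
        r2 = region_rpkm(bam, [GenomicInterval("chr1", 400, 600)])[0]
        assert r2 == pytest.approx(r1 / 2)  # same reads, doubled length

    def test_matches_linear_scan_oracle(self, small_bundle):
        _, ref, exp, _ = small_bundle
        bam = exp.clip_bams[1]
        wc = window_counts(bam, ref.ann.chrom_sizes, 50)
        regions = [
            GenomicInterval("chr1", s, s + 120)
            for s in (800, 5000, 12_000, 20_000)
        ]
        vals = region_rpkm(bam, regions)
        for iv, v in zip(regions, vals):
            n = brute_region_count(bam, iv.chrom, iv.start, iv.end)
            assert v == pytest.approx(n * 1e9 / (len(iv) * wc.library_size))

    def test_zero_length_region_rejected(self, bam_builder):
        bam = _uniform_bam(bam_builder)
        with pytest.raises(ValueError):
            GenomicInterval("chr1", 5, 5)


class TestExonContext:
    @pytest.fixture
    def three_exon_ann(self):
        tx = Transcript(
            "t", "g", "mRNA",
            [
                GenomicInterval("chr1", 100, 200, "+"),
                GenomicInterval("chr1", 400, 500, "+"),
                GenomicInterval("chr1", 700, 800, "+"),
            ],
        )
        tx2 = Transcript(
            "t2", "g2", "mRNA",
            [
                GenomicInterval("chr1", 1000, 1100, "+"),
                GenomicInterval("chr1", 1300, 1400, "+"),
                GenomicInterval("chr1", 1600, 1700, "+"),
            ],
        )
        return GenomeAnnotation([tx, tx2], SIZES)

    def test_focus_equals_background_p_near_one(self, three_exon_ann, bam_builder):
        bam = _uniform_bam(bam_builder, start=100, n=30)
        exons = [GenomicInterval("chr1", 400, 500)]
        comps = compare_exon_context(bam, exons, exons, three_exon_ann)
        assert all(c.p >= 0.99 for c in comps)
        assert {c.region_kind for c in comps} == {
            "flanking_exons", "flanking_introns", "gene_body",
        }

    def test_intron_planting_detected(self, three_exon_ann, bam_builder):
        # pile reads into the introns flanking the middle exon only
        reads = [(f"i{i}", "chr1", 250, "100M", "+") for i in range(60)]
        reads += [(f"j{i}", "chr1", 550, "100M", "+") for i in range(60)]
        reads += [(f"k{i}", "chr1", 1050, "50M", "+") for i in range(5)]
        bam = bam_builder(reads, SIZES)
        focus = [GenomicInterval("chr1", 400, 500)]
        background = [GenomicInterval("chr1", 1300, 1400)]  # second gene
        comps = {c.region_kind: c for c in compare_exon_context(
            bam, focus, background, three_exon_ann)}
        fi = comps["flanking_introns"]
        assert fi.rpkm_focus.mean() > fi.rpkm_background.mean()

    def test_composition_equals_manual_pipeline(self, three_exon_ann, bam_builder):
        bam = _uniform_bam(bam_builder, start=100, n=25)
        focus = [GenomicInterval("chr1", 400, 500)]
        background = [GenomicInterval("chr1", 100, 200)]
        comps = {c.region_kind: c for c in compare_exon_context(
            bam, focus, background, three_exon_ann)}
        gb = comps["gene_body"]
        manual_f = region_rpkm(bam, [GenomicInterval("chr1", 100, 800, "+")])
        u, p = mannwhitney_u(manual_f, manual_f)
        assert gb.rpkm_focus == pytest.approx(manual_f)
        assert gb.p == pytest.approx(p)

    def test_unresolvable_exon_skipped(self, three_exon_ann, bam_builder):
        bam = _uniform_bam(bam_builder, start=100, n=10)
        focus = [GenomicInterval("chr1", 400, 500), GenomicInterval("chr1", 1800, 1900)]
        background = [GenomicInterval("chr1", 100, 200)]
        comps = compare_exon_context(bam, focus, background, three_exon_ann)
        assert all(c.n_skipped == 1 for c in comps)
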