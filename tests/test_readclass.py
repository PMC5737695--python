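"""Priority-table read categorization and junction statistics."""

import numpy as np
import pysam
import pytest

from clipscape.annotation import (
    CLASS_PRIORITY,
    GenomeAnnotation,
    GenomicInterval,
    Transcript,
    build_region_index,
)
from clipscape.readclass import (
    JunctionCounts,
    categorize_read,
    category_distribution,
    compare_junction_ratios,
    junction_counts,
)

from .oracles import cigar_blocks


def _ann(transcripts, sizes):
    return GenomeAnnotation(transcripts, sizes)


def _tx(tx_id, gene, biotype, strand, exon_pairs):
    return Transcript(
        tx_id, gene, biotype,
        [GenomicInterval("chr1", s, e, strand) for s, e in exon_pairs],
    )


@pytest.fixture
def overlap_ann():
    """rRNA gene overlapping an mRNA exon, plus an intron further right."""
    return _ann(
        [
            _tx("r", "gr", "rRNA", "+", [(100, 200)]),
            _tx("m", "gm", "mRNA", "+", [(150, 400), (600, 800)]),
        ],
        {"chr1": 2000},
    )


class TestCategorize:
    def test_priority_rrna_beats_mrna_exon(self, overlap_ann, bam_builder):
        bam = bam_builder([("a", "chr1", 160, "30M", "+")], {"chr1": 2000})
        with pysam.AlignmentFile(bam) as fh:
            read = next(iter(fh))
        cat = categorize_read(read, build_region_index(overlap_ann))
        assert cat.label == "rRNA" and cat.priority == 1

    def test_no_overlap_is_unannotated(self, overlap_ann, bam_builder):
        bam = bam_builder([("a", "chr1", 1500, "30M", "+")], {"chr1": 2000})
        with pysam.AlignmentFile(bam) as fh:
            read = next(iter(fh))
        assert categorize_read(read, build_region_index(overlap_ann)).label == "unannotated"

    def test_spliced_read_skips_intron_class(self, overlap_ann, bam_builder):
        # N gap covers the intron: only exon labels may be assigned
        bam = bam_builder([("a", "chr1", 380, "20M200N20M", "+")], {"chr1": 2000})
        with pysam.AlignmentFile(bam) as fh:
            read = next(iter(fh))
        assert categorize_read(read, build_region_index(overlap_ann)).label == "mRNA exon"

    def test_matches_bruteforce_on_simulated_reads(self, small_bundle):
        """Every read's label equals a brute-force intersection of each
        aligned block against every feature."""
        _, ref, exp, _ = small_bundle
        ann = ref.ann
        index = ann.region_index
        features = []
        for gene_id, txs in ann.genes.items():
            tx = txs[0]
            if tx.biotype == "mRNA":
                for e in tx.exons:
                    features.append(("mRNA exon", e.start, e.end, tx.strand))
                for i in tx.introns:
                    features.append(("mRNA intron", i.start, i.end, tx.strand))
            else:
                for e in tx.exons:
                    features.append((tx.biotype, e.start, e.end, tx.strand))

        def brute(read):
            strand = "-" if read.is_reverse else "+"
            labels = set()
            for bs, be in cigar_blocks(read):
                for label, fs, fe, fstrand in features:
                    if bs < fe and fs < be:
                        if fstrand == strand:
                            labels.add(label)
                        elif label.startswith("mRNA"):
                            labels.add("antisense mRNA")
            if not labels:
                return "unannotated"
            return min(labels, key=lambda l: CLASS_PRIORITY[l])

        with pysam.AlignmentFile(exp.clip_bams[0]) as bam:
            n = 0
            for read in bam:
                assert categorize_read(read, index).label == brute(read)
                n += 1
                if n >= 4000:
                    break


class TestDistribution:
    def test_single_class_bam(self, overlap_ann, bam_builder):
        reads = [(f"r{i}", "chr1", 110, "20M", "+") for i in range(10)]
        bam = bam_builder(reads, {"chr1": 2000})
        frac, counts = category_distribution(bam, build_region_index(overlap_ann))
        assert frac["rRNA"] == 1.0 and counts["rRNA"] == 10

    def test_fractions_sum_to_one(self, small_bundle):
        _, ref, exp, _ = small_bundle
        frac, counts = category_distribution(exp.clip_bams[0], ref.ann.region_index)
        assert sum(frac.values()) == pytest.approx(1.0, abs=1e-9)
        assert sum(counts.values()) == 8000

    def test_empty_bam_raises(self, bam_builder, overlap_ann):
        bam = bam_builder([], {"chr1": 2000})
        with pytest.raises(ValueError, match="zero categorizable"):
            category_distribution(bam, build_region_index(overlap_ann))

    def test_mixture_fractions_near_configured_weights(self, small_bundle):
        """Input-library class mix reflects the configured expression
        weights (rRNA ~26%) within a generous binomial band."""
        _, ref, exp, _ = small_bundle
        frac, _ = category_distribution(exp.input_bams[0], ref.ann.region_index)
        assert abs(frac["rRNA"] - 0.26) < 0.03


class TestJunctions:
    @pytest.fixture
    def two_exon_ann(self):
        return _ann(
            [_tx("m", "gm", "mRNA", "+", [(100, 400), (600, 900)])],
            {"chr1": 2000},
        )

    def test_exon_intron_boundary_read(self, two_exon_ann, bam_builder):
        # 50M crossing the exon end at 400 with 25 bases each side
        bam = bam_builder([("a", "chr1", 375, "50M", "+")], {"chr1": 2000})
        jc = junction_counts(bam, two_exon_ann, min_overhang=5)
        assert (jc.ee, jc.ei) == (0, 1)

    def test_exact_splice_read(self, two_exon_ann, bam_builder):
        # gap [400,600) matches the annotated intron exactly
        bam = bam_builder([("a", "chr1", 380, "20M200N20M", "+")], {"chr1": 2000})
        jc = junction_counts(bam, two_exon_ann, min_overhang=5)
        assert (jc.ee, jc.ei) == (1, 0)

    def test_inexact_gap_not_counted(self, two_exon_ann, bam_builder):
        bam = bam_builder([("a", "chr1", 380, "20M190N20M", "+")], {"chr1": 2000})
        jc = junction_counts(bam, two_exon_ann, min_overhang=5)
        assert (jc.ee, jc.ei) == (0, 0)

    def test_fully_exonic_read_counts_neither(self, two_exon_ann, bam_builder):
        bam = bam_builder([("a", "chr1", 150, "50M", "+")], {"chrl": 2000, "chr1": 2000})
        jc = junction_counts(bam, two_exon_ann, min_overhang=5)
        assert (jc.ee, jc.ei) == (0, 0)

    def test_overhang_enforced(self, two_exon_ann, bam_builder):
        # only 3 bases after the boundary at 400
        bam = bam_builder([("a", "chr1", 353, "50M", "+")], {"chr1": 2000})
        jc = junction_counts(bam, two_exon_ann, min_overhang=5)
        assert jc.ei == 0


class TestCompareRatios:
    def test_identical_groups_give_p_one(self):
        a = [JunctionCounts("a", 9, 1), JunctionCounts("b", 9, 1)]
        res = compare_junction_ratios(a, a)
        assert res.p == 1.0 and res.degenerate

    def test_forced_separation(self):
        clip = [JunctionCounts(f"c{i}", 1, 9) for i in range(3)]
        inp = [JunctionCounts(f"i{i}", 9, 1) for i in range(3)]
        assert compare_junction_ratios(clip, inp).p < 0.01

    def test_detects_precursor_excess_on_simulated_data(self, small_bundle):
        cfg, ref, exp, _ = small_bundle
        clip = [junction_counts(b, ref.ann, 5, str(b)) for b in exp.clip_bams]
        inp = [junction_counts(b, ref.ann, 5, str(b)) for b in exp.input_bams]
        res = compare_junction_ratios(clip, inp)
        assert res.p < 0.05
        assert np.mean([j.ei_fraction for j in clip]) > np.mean(
            [j.ei_fraction for j in inp]
        )
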