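"""Crosslink-site calling, sequence extraction, ZOOPS counting and the
motif enrichment pipeline."""

from collections import Counter

import numpy as np
import pytest

from clipscape.annotation import GenomicInterval
from clipscape.crosslink import (
    CrosslinkSite,
    call_crosslink_sites,
    extract_site_sequences,
    kmer_enrichment,
    kmer_zoops,
    make_background,
    rank_motifs,
    revcomp,
)

from .oracles import brute_pileup, brute_zoops, fisher_enum


class TestSiteCalling:
    def _bam(self, bam_builder, n_cov, n_del, pos=500):
        """n_cov reads covering pos, n_del of them with a 1-nt deletion."""
        reads = []
        for i in range(n_del):
            # 20M1D29M starting 20 before pos: deletion exactly at pos
            reads.append((f"d{i}", "chr1", pos - 20, "20M1D29M", "+"))
        for i in range(n_cov - n_del):
            reads.append((f"m{i}", "chr1", pos - 20, "50M", "+"))
        return bam_builder(reads, {"chr1": 1000})

    def test_five_percent_boundary_called(self, bam_builder):
        bam = self._bam(bam_builder, n_cov=40, n_del=2)  # del_freq exactly 0.05
        sites = call_crosslink_sites(bam, {"chr1": 1000})
        assert any(s.pos == 500 and s.del_freq == pytest.approx(0.05) for s in sites)

    def test_coverage_five_rejected(self, bam_builder):
        bam = self._bam(bam_builder, n_cov=5, n_del=5)
        assert call_crosslink_sites(bam, {"chr1": 1000}) == []

    def test_coverage_six_accepted(self, bam_builder):
        bam = self._bam(bam_builder, n_cov=6, n_del=6)
        sites = call_crosslink_sites(bam, {"chr1": 1000})
        assert any(s.pos == 500 and s.coverage == 6 for s in sites)

    def test_below_frequency_rejected(self, bam_builder):
        bam = self._bam(bam_builder, n_cov=50, n_del=2)  # 4%
        assert call_crosslink_sites(bam, {"chr1": 1000}) == []

    def test_pileup_matches_cigar_walk_oracle(self, small_bundle):
        _, ref, exp, _ = small_bundle
        sizes = ref.ann.chrom_sizes
        sites = call_crosslink_sites(exp.clip_bams[0], sizes)
        cov, dele = brute_pileup(exp.clip_bams[0])
        expected = set()
        for (chrom, strand, pos), d in dele.items():
            c = cov[(chrom, strand, pos)]
            if c >= 6 and d / c >= 0.05:
                expected.add((chrom, pos, strand, c, d))
        got = {(s.chrom, s.pos, s.strand, s.coverage, s.deletions) for s in sites}
        assert got == expected
        assert len(got) > 0


class TestSequenceExtraction:
    GENOME = {"chr1": "ACGTACGTACGTACGTACGTACGTACGT"}

    def test_centered_window(self):
        s = CrosslinkSite("chr1", 13, "+", 10, 1)
        (seq,) = extract_site_sequences([s], self.GENOME, flank=3)
        assert len(seq) == 7
        assert seq == self.GENOME["chr1"][10:17]

    def test_minus_strand_is_reverse_complement(self):
        plus = CrosslinkSite("chr1", 13, "+", 10, 1)
        minus = CrosslinkSite("chr1", 13, "-", 10, 1)
        (p,) = extract_site_sequences([plus], self.GENOME, flank=3)
        (m,) = extract_site_sequences([minus], self.GENOME, flank=3)
        assert m == revcomp(p)

    def test_edge_clamping(self):
        s = CrosslinkSite("chr1", 3, "+", 10, 1)
        (seq,) = extract_site_sequences([s], self.GENOME, flank=10)
        assert seq == self.GENOME["chr1"][0:14]
        assert len(seq) == 14


class TestBackground:
    GENOME = {"chr1": "ACGT" * 300}
    SITES = [CrosslinkSite("chr1", p, "+", 10, 1) for p in (100, 200, 300)]
    REGIONS = [GenomicInterval("chr1", 50, 1000, "+")]

    def test_shuffle_preserves_composition(self):
        fg = extract_site_sequences(self.SITES, self.GENOME, 10)
        bg = make_background(self.SITES, self.REGIONS, self.GENOME, "shuffle", seed=1)
        for f, b in zip(fg, bg):
            assert Counter(f) == Counter(b) and len(f) == len(b)

    def test_sampled_positions_exclude_sites(self):
        rng = np.random.default_rng(0)
        for seed in range(3):
            bg_sites_seqs = make_background(
                self.SITES, self.REGIONS, self.GENOME, "sampled_positions", seed=seed
            )
            assert len(bg_sites_seqs) == 15

    def test_deterministic_given_seed(self):
        a = make_background(self.SITES, self.REGIONS, self.GENOME,
                            "sampled_positions", seed=42)
        b = make_background(self.SITES, self.REGIONS, self.GENOME,
                            "sampled_positions", seed=42)
        assert a == b

    def test_insufficient_positions(self):
        tiny = [GenomicInterval("chr1", 0, 10, "+")]
        with pytest.raises(ValueError, match="eligible"):
            make_background(self.SITES, tiny, self.GENOME, "sampled_positions")


class TestZoops:
    def test_once_per_sequence(self):
        assert kmer_zoops(["ACGACG"], 3)["ACG"] == 1

    def test_counts_across_sequences(self):
        assert kmer_zoops(["ACG", "ACG"], 3)["ACG"] == 2

    def test_n_kmers_skipped(self):
        assert "ANG" not in kmer_zoops(["ANGT"], 3)

    def test_k_longer_than_sequences_warns(self):
        with pytest.warns(UserWarning):
            assert kmer_zoops(["ACG"], 5) == {}

    def test_matches_substring_oracle(self):
        rng = np.random.default_rng(7)
        seqs = [
            "".join(rng.choice(list("ACGT"), size=rng.integers(8, 30)))
            for _ in range(40)
        ]
        for k in (3, 5):
            assert kmer_zoops(seqs, k) == brute_zoops(seqs, k)

    def test_count_never_exceeds_n_sequences(self):
        rng = np.random.default_rng(8)
        seqs = ["".join(rng.choice(list("ACGT"), size=21)) for _ in range(25)]
        assert max(kmer_zoops(seqs, 4).values()) <= len(seqs)


class TestEnrichment:
    def test_known_small_table(self):
        p = kmer_enrichment({"AA": 2}, {}, n_fg=2, n_bg=2)["AA"]
        assert p == pytest.approx(1 / 6, abs=1e-12)

    def test_no_enrichment_direction(self):
        p = kmer_enrichment({"AA": 3}, {"AA": 3}, n_fg=6, n_bg=6)["AA"]
        assert p >= 0.5

    def test_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(3)
        for _ in range(30):
            n_fg = int(rng.integers(2, 11))
            n_bg = int(rng.integers(2, 11))
            fw = int(rng.integers(0, n_fg + 1))
            bw = int(rng.integers(0, n_bg + 1))
            p = kmer_enrichment({"AA": fw}, {"AA": bw}, n_fg, n_bg)["AA"]
            ref = fisher_enum([[fw, n_fg - fw], [bw, n_bg - bw]], "greater")
            assert p == pytest.approx(ref, abs=1e-10)

    def test_counts_exceeding_sizes_rejected(self):
        with pytest.raises(ValueError):
            kmer_enrichment({"AA": 5}, {}, n_fg=3, n_bg=3)


class TestRankMotifs:
    def _fixture(self):
        rng = np.random.default_rng(5)
        genome_seq = "".join(rng.choice(list("ACGT"), size=4000))
        motif = "TCTCC"
        positions = list(range(200, 3400, 200))
        arr = list(genome_seq)
        for p in positions[:10]:  # 10 of 16 sites carry the motif
            arr[p - 2 : p + 3] = motif
        genome = {"chr1": "".join(arr)}
        sites = [CrosslinkSite("chr1", p, "+", 20, 3) for p in positions]
        regions = [GenomicInterval("chr1", 0, 4000, "+")]
        return genome, sites, regions, motif

    def test_planted_kmer_ranked_first(self):
        genome, sites, regions, motif = self._fixture()
        table = rank_motifs([sites] * 3, genome, regions, k_range=(5,), seed=1)
        assert table.table.iloc[0]["kmer"] == motif
        assert table.rank_of(motif) == 1

    def test_replicate_order_invariance(self):
        genome, sites, regions, _ = self._fixture()
        reps = [sites, sites[:12], sites[4:]]
        t1 = rank_motifs(reps, genome, regions, k_range=(4,), seed=2)
        t2 = rank_motifs(list(reversed(reps)), genome, regions, k_range=(4,), seed=2)
        # Fisher's method is symmetric in its inputs and each replicate's
        # background is derived from its own site content, so permuting the
        # replicates leaves ranking and combined p-values identical
        a = t1.table[["kmer", "p_combined"]].reset_index(drop=True)
        b = t2.table[["kmer", "p_combined"]].reset_index(drop=True)
        assert a.equals(b)

    def test_fraction_of_bound_sequences_reported(self):
        genome, sites, regions, motif = self._fixture()
        table = rank_motifs([sites] * 2, genome, regions, k_range=(5,), seed=1)
        row = table.table[table.table.kmer == motif].iloc[0]
        assert row["fg_with"] / row["n_fg"] == pytest.approx(row["fg_fraction"])
        assert row["fg_fraction"] == pytest.approx(10 / 16, abs=0.01)
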