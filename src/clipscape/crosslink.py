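"""Crosslink-site calling from deletion pileups and ZOOPS k-mer motif
enrichment.

Reverse transcription across a protein-RNA crosslink leaves a 1-nt
deletion in the read; positions with >5 reads coverage and a deletion
frequency of at least 5% are called crosslink sites.  Around each site a
flanking sequence is extracted, k-mers are counted zero-or-once per
sequence (ZOOPS) in foreground vs a background set, each replicate is
scored by a one-sided Fisher's exact test, and the per-replicate
p-values are combined by Fisher's method.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import pysam
from scipy import stats as sps

from clipscape.annotation import GenomicInterval
from clipscape.readclass import is_primary
from clipscape.stats import combine_fisher

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class CrosslinkSite:
    chrom: str
    pos: int
    strand: str
    coverage: int
    deletions: int

    @property
    def del_freq(self) -> float:
        return self.deletions / self.coverage


def _pileup_arrays(
    bam_path, chrom_sizes: dict[str, int], stranded: bool = True
) -> dict[tuple[str, str], tuple[np.ndarray, np.ndarray]]:
    """(coverage, deletion) count arrays per (chrom, strand).

    Coverage counts reads whose aligned span (M/=/X and D, excluding N
    gaps) covers the position; deletions count CIGAR D operations.
    """
    out: dict[tuple[str, str], tuple[np.ndarray, np.ndarray]] = {}

    def arrays(chrom: str, strand: str):
        key = (chrom, strand)
        if key not in out:
            n = chrom_sizes[chrom]
            out[key] = (np.zeros(n, dtype=np.int32), np.zeros(n, dtype=np.int32))
        return out[key]

    with pysam.AlignmentFile(str(bam_path)) as bam:
        for read in bam:
            if not is_primary(read):
                continue
            strand = ("-" if read.is_reverse else "+") if stranded else "."
            cov, dele = arrays(read.reference_name, strand)
            pos = read.reference_start
            for op, length in read.cigartuples or ():
                if op in (0, 7, 8):  # M/=/X
                    cov[pos : pos + length] += 1
                    pos += length
                elif op == 2:  # D covers the reference but is a deletion
                    cov[pos : pos + length] += 1
                    dele[pos : pos + length] += 1
                    pos += length
                elif op == 3:  # N: spliced out, no coverage
                    pos += length
    return out


def call_crosslink_sites(
    bam_path,
    chrom_sizes: dict[str, int],
    min_cov: int = 6,
    min_freq: float = 0.05,
    stranded: bool = True,
) -> list[CrosslinkSite]:
    """Positions with coverage > 5 (>= ``min_cov``) and deletion frequency
    >= ``min_freq``.  Deletions longer than 1 nt assign a site to every
    deleted position.  With ``stranded`` (default) pileups are computed per
    read strand."""
    sites = []
    piles = _pileup_arrays(bam_path, chrom_sizes, stranded)
    for (chrom, strand), (cov, dele) in sorted(piles.items()):
        freq = dele / np.maximum(cov, 1)
        called = np.flatnonzero((cov >= min_cov) & (freq >= min_freq))
        for pos in called:
            sites.append(
                CrosslinkSite(chrom, int(pos), strand, int(cov[pos]), int(dele[pos]))
            )
    sites.sort(key=lambda s: (s.chrom, s.pos, s.strand))
    return sites


def extract_site_sequences(
    sites: Sequence[CrosslinkSite], genome, flank: int = 10
) -> list[str]:
    """Flanking sequence [pos-flank, pos+flank+1) per site, on the site
    strand (reverse-complemented for -), truncated at chromosome edges.

    ``genome`` is any mapping chrom -> sliceable sequence (pyfaidx Fasta
    or plain strings)."""
    out = []
    for s in sites:
        chrom_seq = genome[s.chrom]
        lo = max(0, s.pos - flank)
        hi = min(len(chrom_seq), s.pos + flank + 1)
        seq = str(chrom_seq[lo:hi]).upper()
        out.append(revcomp(seq) if s.strand == "-" else seq)
    return out


def make_background(
    sites: Sequence[CrosslinkSite],
    regions: Sequence[GenomicInterval],
    genome,
    mode: str = "sampled_positions",
    seed: int = 0,
    multiple: int = 5,
    flank: int = 10,
) -> list[str]:
    """Background sequence set for motif enrichment.

    mode "shuffle": per-foreground-sequence mononucleotide shuffle
    (length and base composition preserved).  mode "sampled_positions":
    ``multiple`` x |foreground| random positions drawn from the given
    transcript regions, excluding called site positions, same flank.
    """
    rng = np.random.default_rng(seed)
    if mode == "shuffle":
        out = []
        for seq in extract_site_sequences(sites, genome, flank):
            arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
            rng.shuffle(arr)
            out.append(arr.tobytes().decode())
        return out
    if mode != "sampled_positions":
        raise ValueError(f"unknown background mode {mode!r}")

    site_pos = {(s.chrom, s.pos) for s in sites}
    candidates = [
        (iv.chrom, p, iv.strand)
        for iv in regions
        for p in range(iv.start, iv.end)
        if (iv.chrom, p) not in site_pos
    ]
    n = multiple * len(sites)
    if len(candidates) < n:
        raise ValueError(
            f"only {len(candidates)} eligible background positions for {n} requested"
        )
    chosen = rng.choice(len(candidates), size=n, replace=False)
    bg_sites = [
        CrosslinkSite(*candidates[i], coverage=1, deletions=0) for i in sorted(chosen)
    ]
    return extract_site_sequences(bg_sites, genome, flank)


def kmer_zoops(seqs: Iterable[str], k: int) -> dict[str, int]:
    """Zero-or-once-per-sequence k-mer counts; k-mers containing N are
    skipped."""
    if k < 1:
        raise ValueError("k must be >= 1")
    counts: dict[str, int] = {}
    any_long_enough = False
    for seq in seqs:
        if len(seq) >= k:
            any_long_enough = True
        seen = {
            seq[i : i + k]
            for i in range(len(seq) - k + 1)
            if "N" not in seq[i : i + k]
        }
        for kmer in seen:
            counts[kmer] = counts.get(kmer, 0) + 1
    if not any_long_enough:
        warnings.warn(f"k={k} exceeds every sequence length; no k-mers counted")
    return counts


def kmer_enrichment(
    fg_counts: dict[str, int], bg_counts: dict[str, int], n_fg: int, n_bg: int
) -> dict[str, float]:
    """One-sided (enrichment) Fisher exact p per k-mer.

    The 2x2 table is [[fg_with, fg_without], [bg_with, bg_without]]; the
    p-value is the upper hypergeometric tail of fg_with given the fixed
    margins."""
    kmers = sorted(set(fg_counts) | set(bg_counts))
    fg = np.array([fg_counts.get(m, 0) for m in kmers])
    bg = np.array([bg_counts.get(m, 0) for m in kmers])
    if (fg > n_fg).any() or (bg > n_bg).any():
        raise ValueError("counts exceed set sizes")
    # P(X >= fg_with), X ~ Hypergeom(N = n_fg+n_bg, K = fg+bg, n = n_fg)
    p = sps.hypergeom.sf(fg - 1, n_fg + n_bg, fg + bg, n_fg)
    return dict(zip(kmers, p.tolist()))


@dataclass
class MotifTable:
    """Ranked k-mer enrichment table (one row per k-mer)."""

    table: pd.DataFrame

    def top(self, n: int = 10) -> pd.DataFrame:
        return self.table.head(n)

    def rank_of(self, kmer: str) -> int | None:
        """1-based rank of a k-mer in the combined-p ordering."""
        hits = np.flatnonzero(self.table["kmer"].to_numpy() == kmer)
        return int(hits[0]) + 1 if hits.size else None


def rank_motifs(
    per_replicate_sites: Sequence[Sequence[CrosslinkSite]],
    genome,
    regions: Sequence[GenomicInterval],
    k_range: Iterable[int] = (4, 5, 6),
    flank: int = 10,
    background_mode: str = "sampled_positions",
    background_multiple: int = 5,
    seed: int = 0,
) -> MotifTable:
    """Full motif pipeline: per replicate, extract site flanks, build a
    background, ZOOPS-count k-mers and compute one-sided Fisher exact
    p-values; combine replicates by Fisher's method.

    The table is sorted by combined p ascending, ties broken by total
    foreground count (descending) then k-mer lexicographically; it also
    reports the fraction of foreground sequences containing each k-mer
    and a Bonferroni-adjusted combined p (x 4^k per k).
    """
    if not per_replicate_sites:
        raise ValueError("need at least one replicate")
    import zlib

    rep_fg: list[list[str]] = []
    rep_bg: list[list[str]] = []
    for sites in per_replicate_sites:
        # background seed derived from the replicate's site content, so the
        # table is invariant under permutation of the replicates
        key = zlib.crc32(
            repr(sorted((s.chrom, s.pos, s.strand) for s in sites)).encode()
        )
        rep_fg.append(extract_site_sequences(sites, genome, flank))
        rep_bg.append(
            make_background(
                sites, regions, genome, background_mode,
                seed=(seed * 1009 + key) % (2**31),
                multiple=background_multiple, flank=flank,
            )
        )

    rows = []
    for k in k_range:
        per_rep_p: list[dict[str, float]] = []
        per_rep_fg: list[dict[str, int]] = []
        kmers: set[str] = set()
        for fg_seqs, bg_seqs in zip(rep_fg, rep_bg):
            fg_c = kmer_zoops(fg_seqs, k)
            bg_c = kmer_zoops(bg_seqs, k)
            p = kmer_enrichment(fg_c, bg_c, len(fg_seqs), len(bg_seqs))
            per_rep_p.append(p)
            per_rep_fg.append(fg_c)
            kmers |= set(p)
        n_fg_total = sum(len(s) for s in rep_fg)
        for kmer in sorted(kmers):
            plist = [p.get(kmer, 1.0) for p in per_rep_p]
            chi2, df, p_comb = combine_fisher(plist)
            fg_with = sum(c.get(kmer, 0) for c in per_rep_fg)
            rows.append(
                {
                    "kmer": kmer,
                    "k": k,
                    "fg_with": fg_with,
                    "n_fg": n_fg_total,
                    "fg_fraction": fg_with / n_fg_total if n_fg_total else 0.0,
                    **{f"p_rep{i + 1}": p for i, p in enumerate(plist)},
                    "chi2": chi2,
                    "df": df,
                    "p_combined": p_comb,
                    "p_bonferroni": min(1.0, p_comb * 4**k),
                }
            )
    df_out = pd.DataFrame(rows)
    df_out = df_out.sort_values(
        ["p_combined", "fg_with", "kmer"], ascending=[True, False, True]
    ).reset_index(drop=True)
    return MotifTable(df_out)


def sites_to_bed(sites: Sequence[CrosslinkSite], path) -> None:
    """BED6 export, score = round(1000 * deletion frequency)."""
    with open(path, "w") as out:
        for s in sites:
            out.write(
                f"{s.chrom}\t{s.pos}\t{s.pos + 1}\tsite\t"
                f"{round(1000 * s.del_freq)}\t{s.strand}\n"
            )
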