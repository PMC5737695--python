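"""Independent brute-force oracles used to cross-check the pipeline.

These deliberately use different mechanisms from the implementation:
interval trees instead of floor-division window arithmetic, per-position
dictionaries instead of numpy pileup arrays, exact rational enumeration
instead of scipy tails, and full permutation enumeration for rank tests.
"""

from __future__ import annotations

from fractions import Fraction
from itertools import combinations
from math import comb

import pysam
from intervaltree import IntervalTree


def cigar_blocks(read):
    """M/=/X reference blocks computed by a direct CIGAR walk."""
    blocks = []
    pos = read.reference_start
    for op, ln in read.cigartuples or ():
        if op in (0, 7, 8):
            blocks.append((pos, pos + ln))
            pos += ln
        elif op in (2, 3):
            pos += ln
    return blocks


def brute_window_counts(bam_path, chrom_sizes, width):
    """Per-window read counts via an interval tree of window tiles."""
    trees, order = {}, {}
    for chrom, size in chrom_sizes.items():
        t = IntervalTree()
        wins = []
        i = 0
        start = 0
        while start < size:
            end = min(start + width, size)
            t.addi(start, end, i)
            wins.append(0)
            start = end
            i += 1
        trees[chrom] = t
        order[chrom] = wins
    with pysam.AlignmentFile(str(bam_path)) as bam:
        for read in bam:
            if read.is_unmapped or read.is_secondary or read.is_supplementary:
                continue
            tree = trees.get(read.reference_name)
            if tree is None:
                continue
            hit = set()
            for bs, be in cigar_blocks(read):
                for iv in tree.overlap(bs, be):
                    hit.add(iv.data)
            for w in hit:
                order[read.reference_name][w] += 1
    return order


def brute_pileup(bam_path, stranded=True):
    """(coverage, deletion) dicts keyed by (chrom, strand, pos)."""
    cov, dele = {}, {}
    with pysam.AlignmentFile(str(bam_path)) as bam:
        for read in bam:
            if read.is_unmapped or read.is_secondary or read.is_supplementary:
                continue
            strand = ("-" if read.is_reverse else "+") if stranded else "."
            chrom = read.reference_name
            pos = read.reference_start
            for op, ln in read.cigartuples or ():
                if op in (0, 7, 8):
                    for p in range(pos, pos + ln):
                        cov[(chrom, strand, p)] = cov.get((chrom, strand, p), 0) + 1
                    pos += ln
                elif op == 2:
                    for p in range(pos, pos + ln):
                        cov[(chrom, strand, p)] = cov.get((chrom, strand, p), 0) + 1
                        dele[(chrom, strand, p)] = dele.get((chrom, strand, p), 0) + 1
                    pos += ln
                elif op == 3:
                    pos += ln
    return cov, dele


def brute_region_count(bam_path, chrom, start, end):
    """Deduplicated count of block-overlapping reads via a full linear
    scan (no index)."""
    names = set()
    with pysam.AlignmentFile(str(bam_path)) as bam:
        for read in bam:
            if read.is_unmapped or read.is_secondary or read.is_supplementary:
                continue
            if read.reference_name != chrom:
                continue
            if any(bs < end and start < be for bs, be in cigar_blocks(read)):
                names.add(read.query_name)
    return len(names)


def brute_zoops(seqs, k):
    """ZOOPS counts via substring membership over the full k-mer universe
    observed in the sequences."""
    universe = set()
    for s in seqs:
        for i in range(len(s) - k + 1):
            universe.add(s[i : i + k])
    counts = {}
    for kmer in universe:
        if "N" in kmer:
            continue
        n = sum(1 for s in seqs if kmer in s)
        if n:
            counts[kmer] = n
    return counts


# -- exact rational enumeration of Fisher's exact test ----------------------


def _hypergeom_pmf(x, row1, col1, total):
    return Fraction(comb(col1, x) * comb(total - col1, row1 - x), comb(total, row1))


def fisher_enum(table, alternative="two-sided"):
    """Exact Fisher p by enumerating all 2x2 tables with fixed margins."""
    (a, b), (c, d) = table
    row1, col1, total = a + b, a + c, a + b + c + d
    lo = max(0, row1 + col1 - total)
    hi = min(row1, col1)
    p_obs = _hypergeom_pmf(a, row1, col1, total)
    acc = Fraction(0)
    for x in range(lo, hi + 1):
        px = _hypergeom_pmf(x, row1, col1, total)
        if alternative == "greater" and x >= a:
            acc += px
        elif alternative == "less" and x <= a:
            acc += px
        elif alternative == "two-sided" and px <= p_obs:
            acc += px
    return float(acc)


def mwu_enum(x, y):
    """Exact two-sided Mann-Whitney p by full enumeration of group
    assignments (requires no ties)."""
    pooled = sorted(list(x) + list(y))
    assert len(set(pooled)) == len(pooled), "oracle requires no ties"
    n, m = len(x), len(y)
    u_obs = sum(1 for xi in x for yj in y if xi > yj)
    centre = Fraction(n * m, 2)
    dev = abs(Fraction(u_obs) - centre)
    count = total = 0
    for xs in combinations(pooled, n):
        xs_set = set(xs)
        u = sum(1 for xi in xs for yj in pooled if yj not in xs_set and xi > yj)
        total += 1
        if abs(Fraction(u) - centre) >= dev:
            count += 1
    return u_obs, count / total
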