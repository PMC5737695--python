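"""Read categorization by the 12-class priority table and exon-exon vs
exon-intron junction statistics.

A read "overlaps" a class when any of its aligned blocks (CIGAR M/=/X
segments) intersects a feature of that class; N gaps confer no overlap, so
spliced reads do not pick up intron labels.  Among all overlapped classes
the one with the smallest priority number wins; reads overlapping nothing
are "unannotated".
"""

from __future__ import annotations

from dataclasses import dataclass

import pysam

from clipscape.annotation import (
    CLASS_PRIORITY,
    GenomeAnnotation,
    query_classes,
)

_BLOCK_OPS = frozenset((0, 7, 8))  # M, =, X


def aligned_blocks(read: pysam.AlignedSegment) -> list[tuple[int, int]]:
    """Genomic [start, end) spans of the read's M/=/X segments."""
    blocks: list[tuple[int, int]] = []
    pos = read.reference_start
    for op, length in read.cigartuples or ():
        if op in _BLOCK_OPS:
            if blocks and blocks[-1][1] == pos:
                blocks[-1] = (blocks[-1][0], pos + length)
            else:
                blocks.append((pos, pos + length))
            pos += length
        elif op in (2, 3):  # D, N consume reference
            pos += length
    return blocks


def is_primary(read: pysam.AlignedSegment) -> bool:
    return not (read.is_unmapped or read.is_secondary or read.is_supplementary)


@dataclass(frozen=True)
class ReadCategory:
    label: str

    @property
    def priority(self) -> int:
        return CLASS_PRIORITY[self.label]


def categorize_read(read: pysam.AlignedSegment, index) -> ReadCategory | None:
    """Priority-table class of one primary alignment (None = skip signal
    for unmapped/secondary records)."""
    if not is_primary(read):
        return None
    strand = "-" if read.is_reverse else "+"
    labels: set[str] = set()
    for bs, be in aligned_blocks(read):
        labels |= query_classes(index, read.reference_name, bs, be, strand)
    if not labels:
        return ReadCategory("unannotated")
    return ReadCategory(min(labels, key=lambda l: CLASS_PRIORITY[l]))


def category_distribution(
    bam_path, index
) -> tuple[dict[str, float], dict[str, int]]:
    """Fractions and raw counts of reads per RNA class over a BAM.

    Fractions sum to 1 over categorized primary alignments.
    """
    counts = {label: 0 for label in CLASS_PRIORITY}
    total = 0
    with pysam.AlignmentFile(str(bam_path)) as bam:
        for read in bam:
            cat = categorize_read(read, index)
            if cat is None:
                continue
            counts[cat.label] += 1
            total += 1
    if total == 0:
        raise ValueError(f"zero categorizable reads in {bam_path}")
    fractions = {label: n / total for label, n in counts.items()}
    return fractions, counts


@dataclass
class JunctionCounts:
    sample_id: str
    ee: int
    ei: int

    @property
    def ei_fraction(self) -> float | None:
        """EI / (EE + EI); None when no junction reads at all."""
        tot = self.ee + self.ei
        return self.ei / tot if tot else None

    @property
    def ei_over_ee(self) -> float | None:
        return self.ei / self.ee if self.ee else None


def junction_counts(
    bam_path, ann: GenomeAnnotation, min_overhang: int = 5, sample_id: str | None = None
) -> JunctionCounts:
    """Count exon-exon (EE) and exon-intron (EI) junction-spanning reads.

    EE: a spliced read whose N gap matches an annotated intron exactly
    (both splice sites) with >= min_overhang aligned bases on each side.
    EI: a contiguous (no-N) read crossing an annotated exon/intron
    boundary with >= min_overhang bases on each side.  A read counts at
    most once per class.
    """
    if min_overhang < 1:
        raise ValueError("min_overhang must be >= 1")
    introns = ann.introns()
    boundaries: dict[str, list[int]] = {}
    for chrom, s, e in introns:
        boundaries.setdefault(chrom, []).extend((s, e))
    for chrom in boundaries:
        boundaries[chrom] = sorted(set(boundaries[chrom]))

    import bisect

    ee = ei = 0
    with pysam.AlignmentFile(str(bam_path)) as bam:
        for read in bam:
            if not is_primary(read):
                continue
            cig = read.cigartuples or ()
            has_gap = any(op == 3 for op, _ in cig)
            blocks = aligned_blocks(read)
            if not blocks:
                continue
            chrom = read.reference_name
            if has_gap:
                # walk reference to locate each N gap and flanking match
                pos = read.reference_start
                aligned_before = 0
                spans_ee = False
                segs: list[tuple[str, int, int]] = []  # (kind, ref_start, ref_end)
                for op, length in cig:
                    if op in _BLOCK_OPS:
                        segs.append(("M", pos, pos + length))
                        pos += length
                    elif op == 2:
                        segs.append(("D", pos, pos + length))
                        pos += length
                    elif op == 3:
                        segs.append(("N", pos, pos + length))
                        pos += length
                for i, (kind, gs, ge) in enumerate(segs):
                    if kind != "N":
                        continue
                    if (chrom, gs, ge) not in introns:
                        continue
                    left = sum(e - s for k, s, e in segs[:i] if k == "M")
                    right = sum(e - s for k, s, e in segs[i + 1 :] if k == "M")
                    if left >= min_overhang and right >= min_overhang:
                        spans_ee = True
                if spans_ee:
                    ee += 1
            else:
                start, end = blocks[0][0], blocks[-1][1]
                cand = boundaries.get(chrom, [])
                lo = bisect.bisect_left(cand, start + min_overhang)
                hi = bisect.bisect_right(cand, end - min_overhang)
                if lo < hi:
                    ei += 1
    return JunctionCounts(sample_id or str(bam_path), ee, ei)


def compare_junction_ratios(
    clip: list[JunctionCounts], input_: list[JunctionCounts]
):
    """Two-sample two-tailed Student's t-test on per-sample EI/(EE+EI)
    fractions (CLIP vs input).  Returns a TTestResult."""
    from clipscape.stats import student_t

    def fractions(group):
        vals = [jc.ei_fraction for jc in group]
        if any(v is None for v in vals):
            raise ValueError("sample without junction-spanning reads")
        return vals

    return student_t(fractions(clip), fractions(input_))
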