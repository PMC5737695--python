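"""Metagene profiles around strand-oriented anchors, region-level RPKM
and exon-context comparisons.

Coverage is base-level depth from aligned M/=/X blocks (N gaps excluded),
consistent with the read-class overlap semantics.  Profiles are oriented
in the transcription direction: for a minus-strand anchor the window is
reversed so positive offsets point downstream of the anchor.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pysam

from clipscape.annotation import (
    GenomeAnnotation,
    GenomicInterval,
    flatten_exonic_parts,
    read_bed,
)
from clipscape.clusters import RPKM_SCALE
from clipscape.readclass import aligned_blocks, is_primary
from clipscape.stats import mannwhitney_u


@dataclass
class AnchorSet:
    name: str
    anchors: list[tuple[str, int, str]]  # (chrom, position, strand)

    @classmethod
    def from_bed(cls, path, name: str | None = None) -> "AnchorSet":
        anchors = []
        for iv in read_bed(path):
            strand = iv.strand if iv.strand in "+-" else "+"
            anchors.append((iv.chrom, iv.start, strand))
        if not anchors:
            raise ValueError(f"empty anchor set {path}")
        return cls(name or str(path), anchors)


@dataclass
class MetageneProfile:
    offsets: np.ndarray     # -W ... +W in transcription direction
    values: np.ndarray
    n_anchors: int
    n_per_offset: np.ndarray | None = None

    @property
    def argmax_offset(self) -> int:
        return int(self.offsets[int(np.argmax(self.values))])


def _coverage_arrays(bam_path, chrom_sizes: dict[str, int]) -> tuple[dict[str, np.ndarray], int]:
    """Base-level depth per chromosome plus library size (primary reads)."""
    cov = {c: np.zeros(n, dtype=np.float64) for c, n in chrom_sizes.items()}
    lib = 0
    with pysam.AlignmentFile(str(bam_path)) as bam:
        for read in bam:
            if not is_primary(read):
                continue
            lib += 1
            arr = cov.get(read.reference_name)
            if arr is None:
                continue
            for bs, be in aligned_blocks(read):
                arr[bs:be] += 1
    return cov, lib


def _window(cov: np.ndarray, pos: int, W: int, strand: str) -> tuple[np.ndarray, np.ndarray]:
    """(values, defined-mask) for offsets -W..W around pos, oriented."""
    vals = np.zeros(2 * W + 1)
    mask = np.zeros(2 * W + 1, dtype=bool)
    lo = max(0, pos - W)
    hi = min(cov.size, pos + W + 1)
    vals[lo - (pos - W) : hi - (pos - W)] = cov[lo:hi]
    mask[lo - (pos - W) : hi - (pos - W)] = True
    if strand == "-":
        vals = vals[::-1]
        mask = mask[::-1]
    return vals, mask


def anchor_profile(
    bam_paths: Sequence,
    anchors: AnchorSet,
    chrom_sizes: dict[str, int],
    half_window: int = 500,
    normalize: str = "cpm",
) -> MetageneProfile:
    """Mean coverage across anchors at each offset in [-W, +W].

    normalize: "cpm" scales each library to counts per million mapped
    reads before summing; "per_anchor_sum" divides each anchor's window
    by its own total; "none" uses raw depth.  Anchors truncated by a
    chromosome edge contribute only their defined offsets.
    """
    if half_window < 1:
        raise ValueError("half_window must be >= 1")
    if not anchors.anchors:
        raise ValueError("empty anchor set")
    total = {c: np.zeros(n) for c, n in chrom_sizes.items()}
    for path in bam_paths:
        cov, lib = _coverage_arrays(path, chrom_sizes)
        scale = 1e6 / lib if (normalize == "cpm" and lib > 0) else 1.0
        for c in total:
            total[c] += cov[c] * scale

    W = half_window
    acc = np.zeros(2 * W + 1)
    n = np.zeros(2 * W + 1)
    for chrom, pos, strand in anchors.anchors:
        vals, mask = _window(total[chrom], pos, W, strand)
        if normalize == "per_anchor_sum":
            s = vals[mask].sum()
            if s > 0:
                vals = vals / s
        acc += np.where(mask, vals, 0.0)
        n += mask
    values = np.divide(acc, n, out=np.zeros_like(acc), where=n > 0)
    return MetageneProfile(np.arange(-W, W + 1), values, len(anchors.anchors), n)


def coverage_ratio_profile(
    bam_a,
    bam_b,
    anchors: AnchorSet,
    chrom_sizes: dict[str, int],
    half_window: int = 500,
) -> tuple[MetageneProfile, MetageneProfile]:
    """Per-offset ratio of cpm-scaled mean coverage (a / b) around the
    anchors, pseudocounted with each library's cpm of one read.  Returns
    (ratio profile, log2-ratio profile)."""
    prof = {}
    eps = {}
    for key, path in (("a", bam_a), ("b", bam_b)):
        cov, lib = _coverage_arrays(path, chrom_sizes)
        if lib == 0:
            raise ValueError(f"empty BAM {path}")
        scaled = {c: v * 1e6 / lib for c, v in cov.items()}
        W = half_window
        acc = np.zeros(2 * W + 1)
        n = np.zeros(2 * W + 1)
        for chrom, pos, strand in anchors.anchors:
            vals, mask = _window(scaled[chrom], pos, W, strand)
            acc += np.where(mask, vals, 0.0)
            n += mask
        prof[key] = np.divide(acc, n, out=np.zeros_like(acc), where=n > 0)
        eps[key] = 1e6 / lib
    ratio = (prof["a"] + eps["a"]) / (prof["b"] + eps["b"])
    offsets = np.arange(-half_window, half_window + 1)
    n_anchors = len(anchors.anchors)
    return (
        MetageneProfile(offsets, ratio, n_anchors),
        MetageneProfile(offsets, np.log2(ratio), n_anchors),
    )


def region_rpkm(bam_path, regions: Sequence[GenomicInterval]) -> np.ndarray:
    """RPKM per region: overlapping-read count x 1e9 / (length x library
    size).  A read overlaps a region when any aligned block intersects it;
    reads are deduplicated by id within a region."""
    for iv in regions:
        if len(iv) <= 0:
            raise ValueError(f"zero-length region {iv}")
    counts = np.zeros(len(regions), dtype=np.int64)
    lib = 0
    with pysam.AlignmentFile(str(bam_path)) as bam:
        for read in bam:
            if is_primary(read):
                lib += 1
        for i, iv in enumerate(regions):
            names = set()
            for read in bam.fetch(iv.chrom, iv.start, iv.end):
                if not is_primary(read):
                    continue
                if any(bs < iv.end and iv.start < be for bs, be in aligned_blocks(read)):
                    names.add(read.query_name)
            counts[i] = len(names)
    lengths = np.array([len(iv) for iv in regions], dtype=float)
    return counts * RPKM_SCALE / (lengths * max(lib, 1))


@dataclass
class RegionComparison:
    region_kind: str        # flanking_exons | flanking_introns | gene_body
    rpkm_focus: np.ndarray
    rpkm_background: np.ndarray
    u_stat: float
    p: float
    n_skipped: int = 0


def _context_regions(
    ann: GenomeAnnotation, exon: GenomicInterval
) -> dict[str, list[GenomicInterval]] | None:
    """Flanking exonic parts, flanking introns and gene span for the gene
    whose exonic parts contain the exon's midpoint."""
    mid = (exon.start + exon.end) // 2
    for gene_id in ann.genes:
        span = ann.gene_span(gene_id)
        if span.chrom != exon.chrom or not (span.start <= mid < span.end):
            continue
        parts = sorted(flatten_exonic_parts(ann, gene_id), key=lambda p: p.interval.start)
        hit = next(
            (i for i, p in enumerate(parts) if p.interval.start <= mid < p.interval.end),
            None,
        )
        if hit is None:
            continue
        flank_exons = []
        if hit > 0:
            flank_exons.append(parts[hit - 1].interval)
        if hit + 1 < len(parts):
            flank_exons.append(parts[hit + 1].interval)
        flank_introns = []
        if hit > 0:
            a, b = parts[hit - 1].interval.end, parts[hit].interval.start
            if a < b:
                flank_introns.append(GenomicInterval(span.chrom, a, b, span.strand))
        if hit + 1 < len(parts):
            a, b = parts[hit].interval.end, parts[hit + 1].interval.start
            if a < b:
                flank_introns.append(GenomicInterval(span.chrom, a, b, span.strand))
        return {
            "flanking_exons": flank_exons,
            "flanking_introns": flank_introns,
            "gene_body": [span],
        }
    return None


def compare_exon_context(
    bam_path,
    focus_exons: Sequence[GenomicInterval],
    background_exons: Sequence[GenomicInterval],
    ann: GenomeAnnotation,
) -> list[RegionComparison]:
    """CLIP RPKM around a focus exon set vs a background exon set, for
    flanking exons, flanking introns and the whole gene body; each
    contrast is tested with a two-sided Mann-Whitney U.  Exons that
    cannot be resolved to an annotated gene are skipped and counted."""
    kinds = ("flanking_exons", "flanking_introns", "gene_body")
    pooled: dict[str, dict[str, list[GenomicInterval]]] = {
        k: {"focus": [], "background": []} for k in kinds
    }
    skipped = {"focus": 0, "background": 0}
    for group, exons in (("focus", focus_exons), ("background", background_exons)):
        for exon in exons:
            ctx = _context_regions(ann, exon)
            if ctx is None:
                skipped[group] += 1
                continue
            for k in kinds:
                pooled[k][group].extend(ctx[k])

    out = []
    for k in kinds:
        rf = region_rpkm(bam_path, pooled[k]["focus"])
        rb = region_rpkm(bam_path, pooled[k]["background"])
        u, p = mannwhitney_u(rf, rb, alternative="two-sided")
        out.append(
            RegionComparison(k, rf, rb, u, p, skipped["focus"] + skipped["background"])
        )
    return out
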