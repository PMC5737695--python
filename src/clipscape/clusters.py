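"""Window-based binding-cluster calling.

The genome is dissected into fixed-width (default 50 bp) unstranded
windows; per-window RPKM is computed for CLIP replicates and input, and
windows passing an enrichment + coverage filter are merged into clusters.
Two published filter variants are implemented:

* mode "methods": pooled CLIP fold > min_fold AND reads summed across all
  replicates >= min_reads ("minimum of 10 reads ... all three replicates
  summed");
* mode "results" (default): per-replicate fold > min_fold in at least
  min_replicates replicates AND summed reads > min_reads (">10 reads in a
  cluster and >2-fold enrichment ... in at least two replicates").

Fold enrichment is pseudocount-adjusted: fold = (rpkm_clip + eps) /
(rpkm_input + eps) with eps the RPKM of a single read in one window of
the smaller library, so zero-input windows stay finite.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Sequence

import numpy as np
import pysam

from clipscape.annotation import GenomicInterval
from clipscape.readclass import aligned_blocks, is_primary

RPKM_SCALE = 1e9


def tile_windows(
    chrom_sizes: dict[str, int], width: int = 50
) -> Iterator[GenomicInterval]:
    """Non-overlapping adjacent tiles [0,w), [w,2w), ... per chromosome;
    the final partial tile keeps its true width."""
    if width < 1:
        raise ValueError("window width must be >= 1")
    for chrom in sorted(chrom_sizes):
        size = chrom_sizes[chrom]
        for start in range(0, size, width):
            yield GenomicInterval(chrom, start, min(start + width, size))


@dataclass
class WindowCounts:
    """Per-window read counts for one library on a fixed window grid."""

    chrom_sizes: dict[str, int]
    width: int
    counts: dict[str, np.ndarray]   # chrom -> per-window read count
    library_size: int

    def rpkm(self) -> dict[str, np.ndarray]:
        out = {}
        for chrom, c in self.counts.items():
            widths = np.full(c.size, self.width, dtype=float)
            widths[-1] = self.chrom_sizes[chrom] - (c.size - 1) * self.width
            out[chrom] = c * RPKM_SCALE / (widths * max(self.library_size, 1))
        return out


def window_counts(bam_path, chrom_sizes: dict[str, int], width: int = 50) -> WindowCounts:
    """Count reads per window: a read increments every window any of its
    aligned blocks overlaps (bedtools-coverage semantics).  Library size
    is the number of primary mapped alignments."""
    counts = {
        chrom: np.zeros(-(-size // width), dtype=np.int64)
        for chrom, size in chrom_sizes.items()
    }
    library_size = 0
    with pysam.AlignmentFile(str(bam_path)) as bam:
        for read in bam:
            if not is_primary(read):
                continue
            library_size += 1
            arr = counts.get(read.reference_name)
            if arr is None:
                continue
            blocks = aligned_blocks(read)
            if len(blocks) == 1:
                bs, be = blocks[0]
                arr[bs // width : (be - 1) // width + 1] += 1
            else:
                hit: set[int] = set()
                for bs, be in blocks:
                    hit.update(range(bs // width, (be - 1) // width + 1))
                for w in hit:
                    if w < arr.size:
                        arr[w] += 1
    if library_size == 0:
        import warnings

        warnings.warn(f"empty BAM {bam_path}: all window counts zero")
    return WindowCounts(dict(chrom_sizes), width, counts, library_size)


def pool_window_counts(samples: Sequence[WindowCounts]) -> WindowCounts:
    """Pool libraries on a shared grid: counts and library sizes summed."""
    grids = {(tuple(sorted(w.chrom_sizes.items())), w.width) for w in samples}
    if len(grids) != 1:
        raise ValueError("mismatched window grids across samples")
    first = samples[0]
    counts = {
        chrom: sum(w.counts[chrom] for w in samples) for chrom in first.counts
    }
    return WindowCounts(
        dict(first.chrom_sizes), first.width, counts,
        sum(w.library_size for w in samples),
    )


@dataclass
class Cluster:
    interval: GenomicInterval
    n_windows: int
    total_reads: int       # deduplicated CLIP reads summed across replicates
    fold: float
    replicate_support: int


def _pseudocount(width: int, library_sizes: Sequence[int]) -> float:
    return RPKM_SCALE / (width * min(max(l, 1) for l in library_sizes))


def call_clusters(
    clip: Sequence[WindowCounts],
    input_: WindowCounts,
    mode: str = "results",
    min_fold: float = 2.0,
    min_reads: int = 10,
    min_replicates: int = 2,
    max_gap: int = 0,
    clip_bams: Sequence[str] | None = None,
) -> list[Cluster]:
    """Call enriched binding clusters from window scores.

    Passing windows (see module docstring for the two modes) that are
    adjacent on the same chromosome (or separated by at most ``max_gap``
    non-passing windows) are merged; merged read counts deduplicate reads
    by id when the source BAMs are provided, and the merged fold is
    recomputed on the merged counts.
    """
    if mode not in ("methods", "results"):
        raise ValueError(f"unknown mode {mode!r}")
    grids = {(tuple(sorted(w.chrom_sizes.items())), w.width) for w in [*clip, input_]}
    if len(grids) != 1:
        raise ValueError("mismatched window grids across samples")
    width = input_.width

    lib_sizes = [w.library_size for w in clip] + [input_.library_size]
    eps = _pseudocount(width, lib_sizes)
    pooled_lib = sum(w.library_size for w in clip)
    in_rpkm = input_.rpkm()
    clip_rpkm = [w.rpkm() for w in clip]

    clusters: list[Cluster] = []
    for chrom in sorted(input_.counts):
        n_win = input_.counts[chrom].size
        widths = np.full(n_win, width, dtype=float)
        widths[-1] = input_.chrom_sizes[chrom] - (n_win - 1) * width
        summed = sum(w.counts[chrom] for w in clip)
        pooled_rpkm = summed * RPKM_SCALE / (widths * max(pooled_lib, 1))
        pooled_fold = (pooled_rpkm + eps) / (in_rpkm[chrom] + eps)
        rep_fold = np.stack(
            [(r[chrom] + eps) / (in_rpkm[chrom] + eps) for r in clip_rpkm]
        )
        if mode == "methods":
            passing = (pooled_fold > min_fold) & (summed >= min_reads)
        else:
            n_support = (rep_fold > min_fold).sum(axis=0)
            passing = (n_support >= min_replicates) & (summed > min_reads)

        # merge runs of passing windows (allowing max_gap failing windows)
        idx = np.flatnonzero(passing)
        if idx.size == 0:
            continue
        runs: list[tuple[int, int]] = []
        run_start = prev = idx[0]
        for i in idx[1:]:
            if i - prev <= max_gap + 1:
                prev = i
            else:
                runs.append((run_start, prev))
                run_start = prev = i
        runs.append((run_start, prev))

        for a, b in runs:
            start = a * width
            end = min((b + 1) * width, input_.chrom_sizes[chrom])
            iv = GenomicInterval(chrom, start, end)
            if clip_bams is not None:
                total, per_rep = _recount(clip_bams, iv)
            else:
                total = int(summed[a : b + 1].sum())
                per_rep = [int(w.counts[chrom][a : b + 1].sum()) for w in clip]
            length = end - start
            merged_pool = total * RPKM_SCALE / (length * max(pooled_lib, 1))
            in_count = _interval_count(input_.counts[chrom], a, b)
            merged_in = in_count * RPKM_SCALE / (length * max(input_.library_size, 1))
            merged_eps = RPKM_SCALE / (length * min(max(l, 1) for l in lib_sizes))
            fold = (merged_pool + merged_eps) / (merged_in + merged_eps)
            support = 0
            for r, w in enumerate(clip):
                rep_rpkm = per_rep[r] * RPKM_SCALE / (length * max(w.library_size, 1))
                if (rep_rpkm + merged_eps) / (merged_in + merged_eps) > min_fold:
                    support += 1
            clusters.append(Cluster(iv, b - a + 1, total, float(fold), support))
    return clusters


def _interval_count(arr: np.ndarray, a: int, b: int) -> int:
    return int(arr[a : b + 1].sum())


def _recount(bam_paths: Sequence[str], iv: GenomicInterval) -> tuple[int, list[int]]:
    """Deduplicated (by read id) counts of reads whose aligned blocks
    overlap the interval, per BAM and total."""
    per = []
    for path in bam_paths:
        names: set[str] = set()
        with pysam.AlignmentFile(str(path)) as bam:
            for read in bam.fetch(iv.chrom, iv.start, iv.end):
                if not is_primary(read):
                    continue
                if any(bs < iv.end and iv.start < be for bs, be in aligned_blocks(read)):
                    names.add(read.query_name)
        per.append(len(names))
    return sum(per), per


def replicate_overlap(
    per_replicate_clusters: Sequence[Sequence[Cluster]], min_support: int = 2
) -> float:
    """Fraction of clusters with a >=1-bp overlap in at least
    ``min_support - 1`` other replicates, computed per replicate and
    averaged."""
    if len(per_replicate_clusters) < 2:
        raise ValueError("need at least two replicates")
    fractions = []
    for r, own in enumerate(per_replicate_clusters):
        if not own:
            continue
        n_ok = 0
        for cl in own:
            supporters = 0
            for q, other in enumerate(per_replicate_clusters):
                if q == r:
                    continue
                if any(cl.interval.overlaps(o.interval) for o in other):
                    supporters += 1
            if supporters >= min_support - 1:
                n_ok += 1
        fractions.append(n_ok / len(own))
    if not fractions:
        raise ValueError("no clusters in any replicate")
    return float(np.mean(fractions))


def clusters_to_bed(clusters: Sequence[Cluster], path) -> None:
    """BED6 export: name = cluster id, score = min(1000, round(100*fold))."""
    with open(path, "w") as out:
        for i, cl in enumerate(
            sorted(clusters, key=lambda c: (c.interval.chrom, c.interval.start))
        ):
            iv = cl.interval
            score = min(1000, round(100 * cl.fold))
            out.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\tcluster_{i + 1}\t{score}\t.\n"
            )
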