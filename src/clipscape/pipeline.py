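"""End-to-end orchestration of the analysis stages on one simulated (or
real) dataset.  Each stage function writes its tables and returns its
in-memory results; ``run_pipeline`` chains all of them deterministically.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from clipscape.annotation import GenomeAnnotation
from clipscape.clusters import (
    Cluster,
    call_clusters,
    clusters_to_bed,
    pool_window_counts,
    replicate_overlap,
    window_counts,
)
from clipscape.crosslink import (
    CrosslinkSite,
    call_crosslink_sites,
    rank_motifs,
    sites_to_bed,
)
from clipscape.exonstats import (
    direction_summary,
    last_exon_enrichment,
    position_profile,
)
from clipscape.metagene import AnchorSet, anchor_profile, coverage_ratio_profile
from clipscape.readclass import (
    category_distribution,
    compare_junction_ratios,
    junction_counts,
)
from clipscape.simulate import (
    Experiment,
    Reference,
    SimConfig,
    simulate_clip_experiment,
    simulate_exon_de_table,
    simulate_reference,
)


@dataclass
class PipelineResult:
    outdir: Path
    reference: Reference
    experiment: Experiment
    class_fractions: list[dict[str, float]] = field(default_factory=list)
    junction_p: float = float("nan")
    clusters: list[Cluster] = field(default_factory=list)
    overlap_fraction: float = float("nan")
    sites: list[list[CrosslinkSite]] = field(default_factory=list)
    motif_table: pd.DataFrame | None = None
    exonstats: dict | None = None


def stage_simulate(cfg: SimConfig, outdir: Path) -> tuple[Reference, Experiment]:
    ref = simulate_reference(cfg, outdir)
    exp = simulate_clip_experiment(cfg, ref, outdir)
    return ref, exp


def stage_readclass(
    exp: Experiment, ann: GenomeAnnotation, outdir: Path, min_overhang: int = 5
):
    """Class distributions per CLIP replicate and EE/EI junction t-test."""
    index = ann.region_index
    fractions = []
    rows = []
    for bam in exp.clip_bams:
        frac, counts = category_distribution(bam, index)
        fractions.append(frac)
        for label, n in counts.items():
            rows.append(
                {"sample": bam.name, "label": label, "count": n,
                 "fraction": frac[label]}
            )
    pd.DataFrame(rows).to_csv(outdir / "class_distribution.tsv", sep="\t", index=False)

    clip_jc = [junction_counts(b, ann, min_overhang, b.name) for b in exp.clip_bams]
    input_jc = [junction_counts(b, ann, min_overhang, b.name) for b in exp.input_bams]
    res = compare_junction_ratios(clip_jc, input_jc)
    jrows = [
        {"sample": jc.sample_id, "group": grp, "ee": jc.ee, "ei": jc.ei,
         "ei_fraction": jc.ei_fraction, "ei_over_ee": jc.ei_over_ee}
        for grp, group in (("clip", clip_jc), ("input", input_jc))
        for jc in group
    ]
    pd.DataFrame(jrows).to_csv(outdir / "junctions.tsv", sep="\t", index=False)
    return fractions, (clip_jc, input_jc), res


def stage_clusters(
    exp: Experiment,
    outdir: Path,
    mode: str = "results",
    width: int = 50,
    min_fold: float = 2.0,
    min_reads: int = 10,
    min_replicates: int = 2,
):
    """Window counting, cluster calling and replicate reproducibility.

    Input replicates are pooled (counts and library sizes summed) for the
    enrichment denominator.  Replicate overlap follows the unfiltered
    >20-reads convention: per-replicate clusters called with no fold
    filter and a 20-read floor."""
    chrom_sizes = exp.reference.ann.chrom_sizes
    clip_wc = [window_counts(b, chrom_sizes, width) for b in exp.clip_bams]
    input_wc = pool_window_counts(
        [window_counts(b, chrom_sizes, width) for b in exp.input_bams]
    )
    called = call_clusters(
        clip_wc, input_wc, mode=mode, min_fold=min_fold, min_reads=min_reads,
        min_replicates=min_replicates, clip_bams=[str(b) for b in exp.clip_bams],
    )
    clusters_to_bed(called, outdir / "clusters.bed")

    per_rep = [
        call_clusters([wc], input_wc, mode="results", min_fold=0.0,
                      min_reads=20, min_replicates=1)
        for wc in clip_wc
    ]
    overlap = replicate_overlap(per_rep, min_support=2)
    return called, overlap, (clip_wc, input_wc)


def stage_crosslink(
    exp: Experiment,
    outdir: Path,
    k_range=(4, 5, 6),
    flank: int = 10,
    seed: int = 0,
    min_cov: int = 6,
    min_freq: float = 0.05,
):
    """Per-replicate crosslink sites and the combined motif ranking."""
    ref = exp.reference
    chrom_sizes = ref.ann.chrom_sizes
    genome = {c: ref.sequence(c, 0, chrom_sizes[c]) for c in chrom_sizes}
    sites = []
    for i, bam in enumerate(exp.clip_bams):
        s = call_crosslink_sites(bam, chrom_sizes, min_cov, min_freq)
        sites_to_bed(s, outdir / f"xlink_sites_rep{i + 1}.bed")
        sites.append(s)
    regions = [ref.ann.gene_span(g) for g in ref.ann.genes]
    if all(len(s) == 0 for s in sites):
        return sites, None
    table = rank_motifs(sites, genome, regions, k_range, flank=flank, seed=seed)
    table.table.to_csv(outdir / "motifs.tsv", sep="\t", index=False)
    return sites, table


def stage_metagene(exp: Experiment, outdir: Path, half_window: int = 300):
    """CLIP metagene profile around poly(A) anchors and the CLIP/input
    coverage-ratio profile."""
    chrom_sizes = exp.reference.ann.chrom_sizes
    polya = AnchorSet.from_bed(outdir / "polya.bed", "polyA")
    prof = anchor_profile(exp.clip_bams, polya, chrom_sizes, half_window, "cpm")
    ratio, log2ratio = coverage_ratio_profile(
        exp.clip_bams[0], exp.input_bams[0], polya, chrom_sizes, half_window
    )
    pd.DataFrame(
        {"offset": prof.offsets, "clip_cpm": prof.values,
         "clip_over_input": ratio.values, "log2_ratio": log2ratio.values}
    ).to_csv(outdir / "metagene_polya.tsv", sep="\t", index=False)
    return prof, ratio


def stage_exonstats(cfg: SimConfig, ann: GenomeAnnotation, outdir: Path):
    """Synthetic exon-level DE table plus last-exon statistics."""
    de = simulate_exon_de_table(cfg, ann)
    de.to_csv(outdir / "exon_de.tsv", sep="\t", index=False)
    enr = last_exon_enrichment(de)
    dirs = direction_summary(de)
    pos = position_profile(de, max_pos=6)
    pos.to_csv(outdir / "position_profile.tsv", sep="\t", index=False)
    payload = {
        "fisher_table": enr.table.tolist(),
        "odds_ratio": enr.odds_ratio,
        "fisher_p": enr.p,
        "direction_counts": dirs,
    }
    (outdir / "exonstats.json").write_text(json.dumps(payload, indent=1, sort_keys=True))
    return de, enr, dirs


def run_pipeline(cfg: SimConfig, outdir: str | Path) -> PipelineResult:
    """Simulate one experiment and run every analysis stage on it."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ref, exp = stage_simulate(cfg, outdir)
    result = PipelineResult(outdir, ref, exp)

    fractions, _, jres = stage_readclass(exp, ref.ann, outdir)
    result.class_fractions = fractions
    result.junction_p = jres.p

    called, overlap, _ = stage_clusters(exp, outdir)
    result.clusters = called
    result.overlap_fraction = overlap

    sites, motif_table = stage_crosslink(exp, outdir, seed=cfg.seed)
    result.sites = sites
    result.motif_table = motif_table.table if motif_table is not None else None

    stage_metagene(exp, outdir)

    _, enr, dirs = stage_exonstats(cfg, ref.ann, outdir)
    result.exonstats = {
        "fisher_p": enr.p,
        "odds_ratio": enr.odds_ratio,
        "direction_counts": dirs,
    }

    summary = {
        "n_clusters": len(called),
        "replicate_overlap": overlap,
        "junction_t_p": result.junction_p,
        "n_sites_per_replicate": [len(s) for s in sites],
        "top_motif": (
            result.motif_table.iloc[0]["kmer"]
            if result.motif_table is not None and len(result.motif_table)
            else None
        ),
        "last_exon_fisher_p": enr.p,
    }
    (outdir / "summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True))
    return result


def match_clusters(
    called: list[Cluster], truth: list, min_overlap: int = 1
) -> tuple[float, float]:
    """(recall, precision) of called clusters against planted intervals,
    matched by >= 1 bp overlap."""
    def overlaps(a, b):
        return a.chrom == b.chrom and a.start < b.end and b.start < a.end

    truth_ivs = [t.interval for t in truth]
    if not truth_ivs:
        raise ValueError("no planted clusters")
    recall = np.mean(
        [any(overlaps(t, c.interval) for c in called) for t in truth_ivs]
    )
    precision = (
        np.mean([any(overlaps(c.interval, t) for t in truth_ivs) for c in called])
        if called
        else 0.0
    )
    return float(recall), float(precision)
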