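# clipscape

Analysis toolkit for CLIP-seq (UV crosslinking and immunoprecipitation
sequencing) of an m⁶A/m⁶Am demethylase-style RNA-binding protein, with a
deterministic synthetic-data generator that plants ground truth for every
stage.  It is aimed at people who need the classic threshold-based CLIP
analysis stack — read classification, window-based binding-cluster
calling, crosslink-diagnostic motif discovery, metagene profiling and
exon-level differential-expression statistics — as tested, composable
library code rather than one-off scripts.

## What it computes

* **Read classification** — every primary alignment is assigned to one of
  12 RNA classes by a fixed priority table (1. rRNA, 2. tRNA, 3. snoRNA,
  4. snRNA, 5. miRNA, 6. mRNA exon, 7. mRNA intron, 8. mRNA unknown,
  9. lincRNA, 10. repeat, 11. antisense mRNA, 12. unannotated): among all
  classes touched by the read's aligned blocks, the smallest priority
  number wins.
* **Junction statistics** — counts of exon-exon junction reads (spliced
  reads whose N gap matches an annotated intron exactly) versus
  exon-intron boundary reads (contiguous reads crossing a splice site),
  compared between CLIP and input with a two-sample Student's *t*-test on
  per-sample EI/(EE+EI) fractions.  An excess of EI reads in CLIP is the
  signature of pre-mRNA (nuclear) binding.
* **Binding clusters** — the genome is tiled into 50-bp windows and RPKM
  (reads × 10⁹ / (width × library size)) is computed per window for CLIP
  replicates and input.  Windows pass with fold enrichment > 2 and a
  ≥ 10 summed-read floor (two published filter variants, "methods" and
  "results" mode, are both implemented); adjacent passing windows merge
  into clusters.  Fold is pseudocount-adjusted so zero-input windows stay
  finite.
* **Crosslink sites and motifs** — reverse transcription across a
  crosslink leaves a 1-nt deletion; positions with > 5 reads coverage and
  ≥ 5 % deletion frequency are called sites.  Flanking sequences are
  ZOOPS-counted (each sequence contributes a k-mer at most once) against
  a sampled-position background, scored per replicate with a one-sided
  Fisher's exact test, and combined across replicates by Fisher's method
  (χ² = −2 Σ ln pᵢ, df = 2m).
* **Metagene profiles** — strand-oriented coverage around BED anchors
  (TSS, poly(A) sites, …), cpm-normalized, plus coverage-ratio profiles
  between two libraries and region-RPKM contrasts around focus/background
  exon sets (Mann–Whitney *U*).
* **Last-exon statistics** — from an exon-level differential-expression
  table over flattened (DEXSeq-style) exonic parts: a 2×2 Fisher's exact
  test of DE status against last-vs-internal position, up/down direction
  summaries, per-position (from the 3′ end) fold-change profiles, CDF
  comparisons and cross-condition Pearson correlations.

The `simulate` module generates the whole study as synthetic data: a
12-gene ~100 kb genome, sorted/indexed BAMs for three CLIP and three
input replicates, planted 8-fold binding clusters whose centres carry
crosslink deletions and a planted 5-mer, and DE tables with an
upregulation bias at last exons — all byte-identical given a seed.

## Worked example

The numbered drivers under `analysis/` run the full study on the
synthetic fixture (written to `scratch/fixtures/`, tables to `results/`):

```bash
cd analysis
python 01_simulate.py
python 03_binding_clusters.py
python 04_crosslink_motifs.py
```

which prints (seed 0):

```
called 16 clusters (median width 150 bp) -> results/clusters.bed
planted-cluster recovery: recall 1.00, precision 1.00 (16 planted)
replicate overlap (>20-read clusters, >=2 of 3 replicates): 93.1%

crosslink sites per replicate: [18, 17, 22] (16 planted)
planted sites recovered in >=1 replicate: 16/16
top k-mers by combined p:
  TCTCC   k=5 fg 30/57 (53%)  p_combined=6.41e-16
  ...
planted motif 'TCTCC' rank: 1 -> results/motifs.tsv
```

All 16 planted clusters are recovered with no false calls, and the
planted pyrimidine-rich 5-mer ranks first among all k-mers by combined
p-value.  `02_read_classes.py` reports the read-class mixture and the
CLIP-vs-input excess of exon–intron boundary reads (p ≈ 3×10⁻³ here),
`05_metagene_profiles.py` shows the CLIP coverage peak ~100 nt upstream
of poly(A) sites where the exonic clusters were planted, and
`06_last_exon_de.py` reproduces the last-exon upregulation phenotype
(Fisher p ≈ 10⁻¹²⁵, 238 up vs 0 down on the 300-gene table).

The same stages are available as a CLI (`clipscape simulate | classify |
junctions | clusters | crosslink | motifs | metagene | exonstats`) for
use on real BAM/GTF/FASTA inputs.

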