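# Methods

This note records the models, conventions and design choices behind
`clipscape`, in the spirit of the methods documentation that ships with
mature analysis packages.

## Coordinates and annotation model

All internal coordinates are 0-based half-open (BED convention); GTF I/O
converts at the boundary (GTF is 1-based inclusive).  A gene is a set of
transcripts; introns are derived as gaps between consecutive exons, and
for coding transcripts the 5′UTR/CDS/3′UTR lengths partition the mature
length exactly (asserted as an invariant).  Exon-level statistics use
*flattened exonic parts*: all isoform exon boundaries of a gene are
projected onto the genome and the exon union is cut at every internal
boundary, DEXSeq-style.  Parts are numbered from the 5′ end
(`part_number`) and from the 3′ end (`pos_from_3p`, 1 = last); the two
orderings are reverses of each other, and on the minus strand the
leftmost part is the last.

The RNA-class region index stores, per position, every overlapping class
from the 12-entry priority vocabulary.  Conventions the upstream
publication leaves open, resolved here:

* **"mRNA unknown"** is assigned to positions inside an mRNA gene span
  covered by neither exon nor intron of any isoform (e.g. beyond the
  annotated ends of some isoform union).  This is a documented guess at
  an under-specified category, not an inference about upstream intent.
* **Antisense mRNA** is derived at query time: a read whose strand is
  opposite to an overlapping mRNA feature is credited to "antisense
  mRNA".  Opposite-strand ncRNA features are invisible to a read.
* **repeat** intervals come from an optional BED (RepeatMasker-style
  external source); without that file the class is never assigned.

A read "overlaps" a feature when any of its aligned M/=/X blocks
intersects it; N gaps (splices) confer no overlap, so spliced reads do
not collect intron labels.  Among overlapped classes the smallest
priority number wins.

## Cluster calling

Windows are fixed-width (default 50 bp), unstranded, tiled per
chromosome with the final partial tile keeping its true width for RPKM.
RPKM = count × 10⁹ / (width × library size), with library size the
number of primary mapped alignments.  A read increments every window any
of its blocks overlaps (bedtools-coverage semantics); merged clusters
therefore re-count reads deduplicated by id when the source BAMs are
available.

Two published filter variants sit behind `mode`:

* `methods`: pooled fold > `min_fold` AND Σ replicate reads ≥ `min_reads`
  (pooling = counts and library sizes summed before RPKM);
* `results` (default, the variant quoted for the headline cluster count):
  per-replicate fold > `min_fold` in ≥ `min_replicates` replicates AND
  summed reads > `min_reads`.

The inequality directions mirror the published wording exactly:
"enriched >2-fold" is strict, "minimum of 10 reads" is inclusive,
">10 reads" is strict, ">5 reads coverage" is strict and "at least 5% of
deletion frequency" is inclusive.  These boundary semantics are pinned by
dedicated tests.

Fold enrichment is pseudocounted: fold = (rpkm_clip + ε)/(rpkm_input + ε)
with ε the RPKM of a single read in one window of the smallest library
involved.  This keeps zero-input windows finite while strongly damping
fold estimates in sparsely covered windows.  Input replicates are pooled
for the denominator in the pipeline drivers.  Merging joins immediately
adjacent passing windows (`--max-gap` relaxes this); the merged fold is
recomputed on merged, deduplicated counts.

## Crosslink sites and motif discovery

Deletion pileups count, per position and read strand, reads whose
aligned span (M/=/X and D operations, N excluded) covers the position,
and reads with a deletion (D) there.  Deletions longer than 1 nt assign
a site to every deleted position.  Pileups are stranded because CLIP
libraries are; the publication does not state its convention.

Site flanks (default ±10 nt, reverse-complemented on the minus strand)
form the motif foreground.  The background is position-matched: 5× as
many random positions sampled from the same transcript spans, excluding
called sites (a per-sequence mononucleotide shuffle is available as an
alternative).  The upstream work specifies neither flank nor background;
position-matched sampling controls transcript composition, which a pure
shuffle does not.  ZOOPS counting ("zero or once per sequence") is
applied per k-mer, k = 4–6 by default (DRACH-length motifs); k-mers
containing N are skipped.  Per replicate, each k-mer is scored by a
one-sided (enrichment) Fisher's exact test on
[[fg_with, fg_without], [bg_with, bg_without]]; replicate p-values are
combined by Fisher's method (χ² = −2 Σ ln pᵢ, df = 2m; logs summed in
sorted order so the statistic is exactly permutation-invariant).  Each
replicate's background seed derives from its own site content, making
the final table invariant under replicate reordering.  A Bonferroni
column (×4ᵏ per k) is reported alongside the raw combined p used for
ranking, together with the fraction of foreground sequences containing
the k-mer.

## Junction statistics

EE (exon-exon) requires the read's N gap to match an annotated intron at
both splice sites with ≥ `min_overhang` (default 5) aligned bases on each
side; partial splice matches are ignored (conservative, deterministic).
EI (exon-intron) requires a contiguous read crossing an annotated
exon/intron boundary with the same overhang.  A read counts at most once
per class.  The tested quantity is the per-sample fraction EI/(EE+EI) —
more stable than the raw EI:EE ratio when EE can be small — compared
between CLIP and input by a two-tailed two-sample Student's *t*-test;
both the fraction and the raw ratio are emitted.  Zero variance in both
groups with equal means returns p = 1, flagged as degenerate.

## Metagene profiles and region statistics

Coverage is base-level depth from aligned blocks.  Profiles extract
[pos−W, pos+W] around each anchor, reversed for minus-strand anchors so
positive offsets point downstream in transcript direction; anchors
truncated by a chromosome edge contribute only their defined offsets.
Default normalization is cpm (per million mapped reads per library,
summed over libraries); per-anchor sum normalization is available.  The
coverage-ratio profile pseudocounts each library with its own cpm of one
read.  Region RPKM uses deduplicated overlapping-read counts.
Exon-context comparisons resolve each focus/background exon to the gene
whose exonic parts contain its midpoint, pool the two adjacent parts,
the two adjacent introns, and the gene span, and compare focus vs
background RPKM lists with a two-sided Mann–Whitney *U*.

Statistical policies: Mann–Whitney p is exact (full permutation null)
when the pooled sample is ≤ 12 without ties, otherwise the
continuity-corrected normal approximation with tie correction (accurate
to ~0.01 at n = 8 vs 8).  Fisher's exact tests use the point-probability
two-sided convention; the last-exon odds ratio applies a Haldane 0.5
correction when any cell is zero.

## The synthetic-data generator

The generator defines the study conditions; its defaults are the
conditions every test and the acceptance script run under.

* **Genome/annotation** — one 100 kb chromosome, 12 genes tiled without
  overlap: 8 multi-exon mRNAs (3–5 exons of 150–300 bp, introns
  300–700 bp, CDS annotated), one rRNA (1.5 kb), snRNA (160 bp), snoRNA
  (130 bp) and two-exon lincRNA.  Sequence is i.i.d. uniform ACGT except
  planted motif copies.
* **Libraries** — three CLIP and three input replicates of 50,000
  aligned primary reads (50 nt).  Expression weights approximate a
  CLIP-like class mixture (rRNA 26 %, snRNA 5 %, snoRNA 3 %, lincRNA
  4 %, remainder split over mRNAs).  Reads are emitted directly as
  aligned records (splices as N, deletions as D); alignment itself is
  out of scope.  BAMs are sorted in memory and written without a @PG
  line, so outputs are byte-identical across runs.
* **Planted binding** — per mRNA, one 60-bp exonic cluster centred
  100 nt upstream of the transcript 3′ end (so poly(A) metagenes peak
  near −100) and one 60-bp intronic cluster, both 8-fold oversampled in
  CLIP via position-weighted start sampling.  Each cluster centre is a
  crosslink position: CLIP reads covering it acquire a 1-nt deletion
  with probability 0.35 (background deletion rate 2×10⁻³ per read); 60 %
  of crosslink positions carry the pyrimidine-rich 5-mer `TCTCC`
  planted in sense orientation.
* **Precursor fraction** — CLIP 18 % vs input 15 % intron-containing
  precursor reads.  Junction-spanning reads number in the thousands per
  library, so this modest imbalance yields an unambiguous junction
  *t*-test while keeping the genome-wide intron coverage ratio (~1.2×)
  well below the 2-fold cluster threshold: called clusters must come
  from planted binding, not from class composition.  This is a
  deliberate departure from the intron-dominated read mix of real
  nuclear CLIP data, chosen so that cluster calls have a well-defined
  ground truth.
* **DE tables** — per exonic part, null log2FC ~ N(0, 0.15) with uniform
  adjusted p; 80 % of last parts (in multi-part genes) are shifted up by
  +2 with adjusted p in [10⁻¹², 10⁻⁴], and 5 % of internal parts are
  planted DE with a 70 % downward (exon-skipping-like) sign bias.  True
  labels are recorded, so direction summaries can be checked exactly.
* **Randomness** — every stream (genome, each replicate, DE table,
  backgrounds) derives from the single config seed through independent
  `SeedSequence` keys, so adding replicates does not perturb earlier
  outputs.

What the generator does **not** emulate: sequencing errors and quality
strings, PCR duplicates, mappability artefacts, overlapping genes,
alternative isoforms (one transcript per gene by default, so "mRNA
unknown" and multi-isoform flattening are exercised only by dedicated
unit fixtures), and genome-scale feature density.  Passing tests
demonstrate the correctness and calibration of the statistics under
these controlled conditions, not performance on real libraries.

## Problem sizes used by tests and the acceptance script

Unit tests run on a reduced fixture (8,000 reads per replicate).
Recovery and null-control checks run at the full study scale (50,000
reads × 3 replicates) over 10 seeds in the test suite and 5 seeds in the
acceptance script; the last-exon analysis uses a 300-gene annotation
(~1,200 exonic parts) so the Fisher table is well populated.  The
end-to-end determinism check runs the complete pipeline twice at 10,000
reads per replicate and compares all output files byte for byte.

## Known limitations

* The cluster caller is pure thresholding (as published): no Poisson/NB
  significance model and no multiple-testing control across windows.
* ZOOPS is applied to ±10 nt site flanks; if "per transcript" counting
  over full transcript sequences were intended upstream, enrichment
  granularity would differ.
* The two published filter variants ("methods" vs "results") disagree;
  both are implemented and neither is asserted canonical.
* Exact Mann–Whitney enumeration is limited to pooled n ≤ 12; beyond
  that the normal approximation's ~1 % error applies.
* Windows are unstranded genome tiles, as published ("dissected the
  genome"); crosslink-site calling, by contrast, is stranded.  A
  strand-aware window mode was considered and not implemented: with
  stranded site calling downstream it adds no ground-truth power on
  these data.
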