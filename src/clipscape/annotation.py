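"""Genome annotation: interval types, GTF I/O, prioritized RNA-class region
index and DEXSeq-style flattened exonic parts.

Internal coordinates are 0-based half-open (BED convention); the GTF reader
and writer convert at the boundary.  The RNA-class vocabulary follows the
12-entry priority table used to categorize CLIP reads (1. rRNA, 2. tRNA,
3. snoRNA, 4. snRNA, 5. miRNA, 6. mRNA exon, 7. mRNA intron, 8. mRNA
unknown, 9. lincRNA, 10. repeat, 11. antisense mRNA, 12. unannotated).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import gffutils
from intervaltree import IntervalTree
from pyfaidx import Fasta

#: priority table: smaller number wins when a read overlaps several classes
CLASS_PRIORITY: dict[str, int] = {
    "rRNA": 1,
    "tRNA": 2,
    "snoRNA": 3,
    "snRNA": 4,
    "miRNA": 5,
    "mRNA exon": 6,
    "mRNA intron": 7,
    "mRNA unknown": 8,
    "lincRNA": 9,
    "repeat": 10,
    "antisense mRNA": 11,
    "unannotated": 12,
}

NCRNA_BIOTYPES = ("rRNA", "tRNA", "snoRNA", "snRNA", "miRNA", "lincRNA")


class AnnotationError(Exception):
    """Raised on malformed or inconsistent annotation input."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open genomic interval [start, end) on a named chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval [{self.start}, {self.end})")
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass
class Transcript:
    id: str
    gene_id: str
    biotype: str
    exons: list[GenomicInterval]
    cds_start: int | None = None
    cds_end: int | None = None

    def __post_init__(self) -> None:
        self.exons = sorted(self.exons, key=lambda e: e.start)
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start < a.end:
                raise AnnotationError(
                    f"overlapping exons in transcript {self.id}: {a} / {b}"
                )

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def start(self) -> int:
        return self.exons[0].start

    @property
    def end(self) -> int:
        return self.exons[-1].end

    @property
    def introns(self) -> list[GenomicInterval]:
        """Gaps between consecutive exons."""
        return [
            GenomicInterval(self.chrom, a.end, b.start, self.strand)
            for a, b in zip(self.exons, self.exons[1:])
            if b.start > a.end
        ]

    @property
    def spliced_length(self) -> int:
        return sum(len(e) for e in self.exons)

    def utr_cds_lengths(self) -> tuple[int, int, int] | None:
        """(5'UTR, CDS, 3'UTR) lengths on the mature transcript, or None
        when no CDS is annotated.  The three lengths partition the mature
        length exactly."""
        if self.cds_start is None or self.cds_end is None:
            return None
        before = after = cds = 0
        for e in self.exons:
            before += max(0, min(e.end, self.cds_start) - e.start)
            cds += max(0, min(e.end, self.cds_end) - max(e.start, self.cds_start))
            after += max(0, e.end - max(e.start, self.cds_end))
        if self.strand == "-":
            before, after = after, before
        return before, cds, after


@dataclass(frozen=True)
class ExonicPart:
    """One disjoint exonic bin of a gene (boundary-split isoform union)."""

    gene_id: str
    interval: GenomicInterval
    part_number: int      # ordinal from the 5' end, 1-based
    pos_from_3p: int      # ordinal from the 3' end, 1 = last
    is_last: bool

    @property
    def part_id(self) -> str:
        return f"{self.gene_id}:E{self.part_number:03d}"


@dataclass
class GenomeAnnotation:
    transcripts: list[Transcript]
    chrom_sizes: dict[str, int]
    repeats: list[GenomicInterval] = field(default_factory=list)
    _index: dict[str, IntervalTree] | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        for tx in self.transcripts:
            size = self.chrom_sizes.get(tx.chrom)
            if size is not None and tx.end > size:
                raise AnnotationError(
                    f"transcript {tx.id} extends past chromosome "
                    f"{tx.chrom} (end {tx.end} > {size})"
                )

    @property
    def genes(self) -> dict[str, list[Transcript]]:
        out: dict[str, list[Transcript]] = {}
        for tx in self.transcripts:
            out.setdefault(tx.gene_id, []).append(tx)
        return out

    def gene_span(self, gene_id: str) -> GenomicInterval:
        txs = self.genes.get(gene_id)
        if not txs:
            raise KeyError(f"unknown gene_id {gene_id!r}")
        return GenomicInterval(
            txs[0].chrom,
            min(t.start for t in txs),
            max(t.end for t in txs),
            txs[0].strand,
        )

    def introns(self) -> set[tuple[str, int, int]]:
        """All annotated introns as (chrom, start, end)."""
        return {
            (i.chrom, i.start, i.end) for tx in self.transcripts for i in tx.introns
        }

    @property
    def region_index(self) -> dict[str, IntervalTree]:
        if self._index is None:
            self._index = build_region_index(self)
        return self._index


def _validate_gtf_lines(path: Path) -> None:
    """Cheap structural scan so parse errors can name the offending line."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 9:
                raise AnnotationError(
                    f"malformed GTF line {lineno}: expected 9 tab-separated "
                    f"fields, got {len(fields)}"
                )
            try:
                start, end = int(fields[3]), int(fields[4])
            except ValueError as exc:
                raise AnnotationError(
                    f"malformed GTF line {lineno}: non-integer coordinates"
                ) from exc
            if start < 1 or end < start:
                raise AnnotationError(
                    f"malformed GTF line {lineno}: bad coordinate range "
                    f"{start}-{end}"
                )


def load_annotation(
    gtf_path: str | Path,
    fasta_path: str | Path | None = None,
    repeats_bed: str | Path | None = None,
) -> GenomeAnnotation:
    """Load a GTF (Ensembl dialect: gene_id / transcript_id / gene_biotype
    attributes) into a :class:`GenomeAnnotation`.

    GTF 1-based inclusive coordinates are converted to 0-based half-open.
    Chromosome sizes come from the FASTA index when ``fasta_path`` is given,
    otherwise from the maximum feature end per chromosome.  An optional BED
    of repeat intervals populates the "repeat" class; without it the class
    is never assigned.
    """
    gtf_path = Path(gtf_path)
    _validate_gtf_lines(gtf_path)
    db = gffutils.create_db(
        str(gtf_path),
        ":memory:",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
        keep_order=True,
    )

    exons: dict[str, list] = {}
    cds: dict[str, list] = {}
    meta: dict[str, tuple[str, str]] = {}
    for feat in db.all_features():
        if feat.featuretype not in ("exon", "CDS"):
            continue
        tx_id = feat.attributes["transcript_id"][0]
        gene_id = feat.attributes["gene_id"][0]
        biotype = feat.attributes.get("gene_biotype", ["mRNA"])[0]
        if biotype in ("protein_coding",):
            biotype = "mRNA"
        meta[tx_id] = (gene_id, biotype)
        bucket = exons if feat.featuretype == "exon" else cds
        bucket.setdefault(tx_id, []).append(feat)

    transcripts = []
    for tx_id, feats in exons.items():
        gene_id, biotype = meta[tx_id]
        ivs = [
            GenomicInterval(f.seqid, f.start - 1, f.end, f.strand) for f in feats
        ]
        cstart = cend = None
        if tx_id in cds:
            cstart = min(f.start - 1 for f in cds[tx_id])
            cend = max(f.end for f in cds[tx_id])
        transcripts.append(Transcript(tx_id, gene_id, biotype, ivs, cstart, cend))
    transcripts.sort(key=lambda t: (t.chrom, t.start, t.id))

    if fasta_path is not None:
        fa = Fasta(str(fasta_path))
        chrom_sizes = {name: len(fa[name]) for name in fa.keys()}
    else:
        chrom_sizes = {}
        for tx in transcripts:
            chrom_sizes[tx.chrom] = max(chrom_sizes.get(tx.chrom, 0), tx.end)

    repeats: list[GenomicInterval] = []
    if repeats_bed is not None:
        repeats = list(read_bed(repeats_bed))

    return GenomeAnnotation(transcripts, chrom_sizes, repeats)


def write_gtf(ann: GenomeAnnotation, path: str | Path) -> None:
    """Write annotation back to GTF (exon and CDS features)."""
    with open(path, "w") as out:
        for tx in ann.transcripts:
            attrs = (
                f'gene_id "{tx.gene_id}"; transcript_id "{tx.id}"; '
                f'gene_biotype "{tx.biotype}";'
            )
            for e in tx.exons:
                out.write(
                    f"{e.chrom}\tclipscape\texon\t{e.start + 1}\t{e.end}\t.\t"
                    f"{e.strand}\t.\t{attrs}\n"
                )
            if tx.cds_start is not None and tx.cds_end is not None:
                for e in tx.exons:
                    s = max(e.start, tx.cds_start)
                    t = min(e.end, tx.cds_end)
                    if s < t:
                        out.write(
                            f"{e.chrom}\tclipscape\tCDS\t{s + 1}\t{t}\t.\t"
                            f"{e.strand}\t.\t{attrs}\n"
                        )


def read_bed(path: str | Path) -> Iterator[GenomicInterval]:
    """Read BED3/BED6 intervals (0-based half-open, as BED defines)."""
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.rstrip("\n").split("\t")
            strand = f[5] if len(f) > 5 else "."
            yield GenomicInterval(f[0], int(f[1]), int(f[2]), strand)


def write_bed(
    intervals: Iterable[tuple[GenomicInterval, str, float]], path: str | Path
) -> None:
    """Write (interval, name, score) triples as BED6."""
    with open(path, "w") as out:
        for iv, name, score in intervals:
            out.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{score:g}\t{iv.strand}\n"
            )


def flatten_exonic_parts(ann: GenomeAnnotation, gene_id: str) -> list[ExonicPart]:
    """Project all isoform exon boundaries of a gene onto the genome and cut
    the exon union into disjoint parts (DEXSeq-style counting bins).

    ``part_number`` counts from the 5' end in transcription order;
    ``pos_from_3p`` counts from the 3' end (1 = last part).  On the minus
    strand the leftmost part is therefore pos_from_3p = 1.
    """
    txs = ann.genes.get(gene_id)
    if not txs:
        raise KeyError(f"unknown gene_id {gene_id!r}")
    strand = txs[0].strand
    chrom = txs[0].chrom
    exons = sorted(
        ((e.start, e.end) for tx in txs for e in tx.exons), key=lambda x: x
    )

    # union of exons
    union: list[list[int]] = []
    for s, e in exons:
        if union and s <= union[-1][1]:
            union[-1][1] = max(union[-1][1], e)
        else:
            union.append([s, e])

    boundaries = sorted({c for s, e in exons for c in (s, e)})
    parts_iv: list[GenomicInterval] = []
    for us, ue in union:
        cuts = [c for c in boundaries if us < c < ue]
        edges = [us, *cuts, ue]
        for a, b in zip(edges, edges[1:]):
            parts_iv.append(GenomicInterval(chrom, a, b, strand))

    n = len(parts_iv)
    out = []
    for i, iv in enumerate(parts_iv):  # left to right
        number = i + 1 if strand != "-" else n - i
        from3p = n - number + 1
        out.append(ExonicPart(gene_id, iv, number, from3p, from3p == 1))
    out.sort(key=lambda p: p.part_number)
    return out


def build_region_index(ann: GenomeAnnotation) -> dict[str, IntervalTree]:
    """Per-chromosome interval tree mapping positions to RNA-class labels.

    Each tree interval carries ``(label, gene_id, strand)``.  mRNA loci are
    decomposed into exon / intron / unknown (gene span not covered by any
    isoform's exons or introns); ncRNA biotypes contribute their exons under
    the biotype label; repeat intervals come from the optional repeat BED.
    Antisense labelling is derived at query time from the strand stored here.
    """
    trees: dict[str, IntervalTree] = {}

    def add(chrom: str, start: int, end: int, label: str, gene: str, strand: str):
        if end > start:
            trees.setdefault(chrom, IntervalTree()).addi(
                start, end, (label, gene, strand)
            )

    for gene_id, txs in ann.genes.items():
        strand = txs[0].strand
        chrom = txs[0].chrom
        biotype = txs[0].biotype
        if biotype in NCRNA_BIOTYPES:
            for tx in txs:
                for e in tx.exons:
                    add(chrom, e.start, e.end, biotype, gene_id, strand)
            continue
        # mRNA: exon beats intron where isoforms disagree
        covered: set[int] = set()
        for tx in txs:
            for e in tx.exons:
                add(chrom, e.start, e.end, "mRNA exon", gene_id, strand)
                covered.update(range(e.start, e.end))
        for tx in txs:
            for i in tx.introns:
                add(chrom, i.start, i.end, "mRNA intron", gene_id, strand)
                covered.update(range(i.start, i.end))
        span = ann.gene_span(gene_id)
        for pos in range(span.start, span.end):
            if pos not in covered:
                add(chrom, pos, pos + 1, "mRNA unknown", gene_id, strand)

    for iv in ann.repeats:
        add(iv.chrom, iv.start, iv.end, "repeat", "repeat", ".")
    return trees


def query_classes(
    index: dict[str, IntervalTree],
    chrom: str,
    start: int,
    end: int,
    read_strand: str | None = None,
) -> set[str]:
    """Class labels overlapping [start, end).

    With ``read_strand`` given, same-strand (or unstranded) features report
    their own label while an opposite-strand mRNA feature reports
    "antisense mRNA"; opposite-strand ncRNA features are invisible.
    """
    tree = index.get(chrom)
    if tree is None:
        return set()
    labels: set[str] = set()
    for hit in tree.overlap(start, end):
        label, _gene, strand = hit.data
        if read_strand is None or strand == "." or strand == read_strand:
            labels.add(label)
        elif label.startswith("mRNA"):
            labels.add("antisense mRNA")
    return labels


def write_db(ann: GenomeAnnotation, path: str | Path) -> None:
    """Persist the annotation as a GTF next to a chrom-sizes sidecar."""
    path = Path(path)
    write_gtf(ann, path)
    with open(path.with_suffix(path.suffix + ".chrom"), "w") as out:
        for chrom, size in sorted(ann.chrom_sizes.items()):
            out.write(f"{chrom}\t{size}\n")
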