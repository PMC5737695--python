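"""Shared fixtures: one small simulated experiment per session plus a toy
BAM builder for hand-constructed reads."""

from __future__ import annotations

from pathlib import Path

import pysam
import pytest

from clipscape.annotation import load_annotation
from clipscape.simulate import SimConfig, simulate_clip_experiment, simulate_reference

SMALL_CFG = SimConfig(seed=101, library_size_clip=8000, library_size_input=8000)


@pytest.fixture(scope="session")
def small_bundle(tmp_path_factory):
    """Reduced-size simulated experiment shared across unit tests."""
    outdir = tmp_path_factory.mktemp("smallsim")
    ref = simulate_reference(SMALL_CFG, outdir)
    exp = simulate_clip_experiment(SMALL_CFG, ref, outdir)
    return SMALL_CFG, ref, exp, Path(outdir)


@pytest.fixture(scope="session")
def small_ann(small_bundle):
    _, ref, _, _ = small_bundle
    return ref.ann


@pytest.fixture(scope="session")
def loaded_ann(small_bundle):
    """The same annotation, but parsed back from the emitted GTF/FASTA."""
    _, _, _, outdir = small_bundle
    return load_annotation(outdir / "annotation.gtf", outdir / "genome.fa")


def make_bam(path, reads, chrom_sizes, genome=None):
    """Write a coordinate-sorted indexed BAM from (name, chrom, start,
    cigar, strand) tuples.  Query sequence is taken from ``genome`` when
    given, else filled with 'A'."""
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": c, "LN": n} for c, n in sorted(chrom_sizes.items())],
    }
    h = pysam.AlignmentHeader.from_dict(header)
    tid = {c: i for i, (c, _) in enumerate(sorted(chrom_sizes.items()))}
    segs = []
    for name, chrom, start, cigar, strand in reads:
        a = pysam.AlignedSegment(h)
        a.query_name = name
        a.reference_id = tid[chrom]
        a.reference_start = start
        a.cigarstring = cigar
        a.flag = 16 if strand == "-" else 0
        a.mapping_quality = 255
        qlen = a.infer_query_length()
        if genome is not None:
            pos, parts = start, []
            for op, ln in a.cigartuples:
                if op in (0, 7, 8):
                    parts.append(str(genome[chrom][pos : pos + ln]))
                    pos += ln
                elif op in (2, 3):
                    pos += ln
                elif op == 1:
                    parts.append("A" * ln)
            a.query_sequence = "".join(parts)
        else:
            a.query_sequence = "A" * qlen
        segs.append(a)
    segs.sort(key=lambda r: (r.reference_id, r.reference_start, r.query_name))
    path = str(path)
    with pysam.AlignmentFile(path, "wb", header=header) as out:
        for a in segs:
            out.write(a)
    pysam.index(path)
    return path


@pytest.fixture
def bam_builder(tmp_path):
    def build(reads, chrom_sizes, genome=None, name="toy.bam"):
        return make_bam(tmp_path / name, reads, chrom_sizes, genome)

    return build
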