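"""Shared fixtures: tiny genomes, hand-built SAM files, random chain makers."""

from __future__ import annotations

import numpy as np
import pysam
import pytest

from lrannot.models import Annotation, TranscriptModel
from lrannot.profile import GenomeAccessor, MappedReadAlignment


@pytest.fixture
def flat_genome():
    """5 kb of all-G so any planted base differs visibly."""
    return GenomeAccessor({"chr1": "G" * 5000})


@pytest.fixture
def sam_factory(tmp_path):
    """Write a SAM file from (name, flag, chrom, pos, cigar, seq) tuples."""

    def build(records, chroms=None, sort_order="coordinate", filename="reads.sam"):
        chroms = chroms or {"chr1": 10000, "chr2": 10000}
        header = pysam.AlignmentHeader.from_dict(
            {
                "HD": {"VN": "1.6", "SO": sort_order},
                "SQ": [{"SN": c, "LN": ln} for c, ln in chroms.items()],
            }
        )
        path = tmp_path / filename
        with pysam.AlignmentFile(str(path), "w", header=header) as out:
            for name, flag, chrom, pos, cigar, seq in records:
                rec = pysam.AlignedSegment(header)
                rec.query_name = name
                rec.flag = flag
                if chrom is not None:
                    rec.reference_name = chrom
                    rec.reference_start = pos
                    rec.cigarstring = cigar
                rec.query_sequence = seq
                rec.mapping_quality = 60
                out.write(rec)
        return path

    return build


def make_alignment(
    read_id: str,
    blocks,
    strand: str = "+",
    chrom: str = "chr1",
    events=(),
    identity: float = 1.0,
    coverage: float = 1.0,
) -> MappedReadAlignment:
    length = sum(e - s for s, e in blocks)
    return MappedReadAlignment(
        read_id=read_id,
        chrom=chrom,
        strand=strand,
        blocks=tuple(blocks),
        events=tuple(events),
        read_length=length,
        mapped_span=length,
        identity=identity,
        coverage=coverage,
    )


def make_model(tid, exons, strand="+", chrom="chr1", gene=None) -> TranscriptModel:
    return TranscriptModel(
        chrom=chrom,
        strand=strand,
        exons=tuple(exons),
        transcript_id=tid,
        gene_id=gene or tid.split(".")[0],
    )


def random_chain(rng: np.random.Generator, origin: int = 0, max_exons: int = 4):
    """Random plausible exon chain near ``origin`` for oracle tests."""
    n = int(rng.integers(1, max_exons + 1))
    pos = origin + int(rng.integers(0, 40))
    exons = []
    for i in range(n):
        length = int(rng.integers(30, 120))
        exons.append((pos, pos + length))
        pos += length + int(rng.integers(50, 200))
    return tuple(exons)


@pytest.fixture
def three_exon_annotation():
    models = [
        make_model("G1.1", [(100, 200), (400, 500), (700, 800)], gene="G1"),
        make_model("G1.2", [(100, 200), (700, 800)], gene="G1"),
        make_model("G2.1", [(2000, 2300)], strand="-", gene="G2"),
    ]
    return Annotation.from_models(models)
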