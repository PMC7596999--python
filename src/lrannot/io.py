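"""Readers and writers for the formats every stage touches.

BED12 is the toolkit's native annotation dialect: the name field carries
``gene_id;transcript_id``.  All coordinates are kept 0-based half-open
internally; GTF (1-based, inclusive) is converted at this boundary only.
Alignments are read through pysam and must be coordinate-sorted.
"""

from __future__ import annotations

import os
from pathlib import Path
from typing import Iterable, Iterator

import pysam

from .models import Annotation, TranscriptModel


class ParseError(ValueError):
    pass


# ---------------------------------------------------------------------------
# BED12
# ---------------------------------------------------------------------------

def _parse_name(name: str) -> tuple[str, str]:
    # tolerant reading of non-dialect BEDs: bare name -> gene == transcript
    if ";" in name:
        gene_id, transcript_id = name.split(";", 1)
        return gene_id, transcript_id
    return name, name


def read_bed12(path: str | os.PathLike) -> Annotation:
    """Read a BED12 annotation whose name field is ``gene_id;transcript_id``."""
    models: list[TranscriptModel] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) == 1:
                fields = line.split()
            if len(fields) < 12:
                raise ParseError(f"{path}:{lineno}: expected 12 BED fields, got {len(fields)}")
            try:
                chrom = fields[0]
                start = int(fields[1])
                end = int(fields[2])
                gene_id, transcript_id = _parse_name(fields[3])
                strand = fields[5]
                block_count = int(fields[9])
                sizes = [int(x) for x in fields[10].rstrip(",").split(",")]
                starts = [int(x) for x in fields[11].rstrip(",").split(",")]
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            if strand not in ("+", "-"):
                raise ParseError(
                    f"{path}:{lineno}: strand {strand!r} not allowed; grouping is strand-aware"
                )
            if len(sizes) != block_count or len(starts) != block_count:
                raise ParseError(
                    f"{path}:{lineno}: blockCount {block_count} does not match "
                    f"{len(sizes)} sizes / {len(starts)} starts"
                )
            exons = tuple((start + bs, start + bs + sz) for bs, sz in zip(starts, sizes))
            if exons[0][0] != start or exons[-1][1] != end:
                raise ParseError(f"{path}:{lineno}: blocks do not span chromStart..chromEnd")
            models.append(
                TranscriptModel(
                    chrom=chrom,
                    strand=strand,
                    exons=exons,
                    transcript_id=transcript_id,
                    gene_id=gene_id,
                )
            )
    return Annotation.from_models(models)


def write_bed12(annotation: Annotation, path: str | os.PathLike) -> None:
    """Write BED12 with deterministic (chrom, start, transcript_id) ordering.

    Score and RGB are fixed placeholders (40, "255,0,0"); thickStart/End
    mirror the transcript span.
    """
    with open(path, "w") as fh:
        for m in annotation.sorted():
            sizes = ",".join(str(e - s) for s, e in m.exons)
            starts = ",".join(str(s - m.start) for s, _ in m.exons)
            fh.write(
                "\t".join(
                    [
                        m.chrom,
                        str(m.start),
                        str(m.end),
                        f"{m.gene_id};{m.transcript_id}",
                        "40",
                        m.strand,
                        str(m.start),
                        str(m.end),
                        "255,0,0",
                        str(m.n_exons),
                        sizes,
                        starts,
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# GTF
# ---------------------------------------------------------------------------

def _gtf_attributes(text: str) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for chunk in text.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        if " " not in chunk:
            continue
        key, value = chunk.split(" ", 1)
        attrs[key] = value.strip().strip('"')
    return attrs


def read_gtf(path: str | os.PathLike) -> Annotation:
    """Read a GTF annotation into one model per transcript_id.

    Only ``exon`` features are consulted.  Coordinates are converted from
    1-based inclusive to 0-based half-open.  Exons are re-sorted ascending
    regardless of file order (minus-strand GTFs often list them 3'->5').
    Transcripts that never appear on an exon line are skipped and counted
    in the returned annotation's ``skipped`` attribute.
    """
    exons: dict[str, list[tuple[int, int]]] = {}
    meta: dict[str, tuple[str, str, str]] = {}
    declared: set[str] = set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            if not raw.strip() or raw.startswith("#"):
                continue
            fields = raw.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise ParseError(f"{path}:{lineno}: expected 9 GTF columns")
            chrom, _src, feature, start, end, _score, strand, _frame, attr_text = fields[:9]
            attrs = _gtf_attributes(attr_text)
            tid = attrs.get("transcript_id")
            if tid is None:
                continue
            if feature == "transcript":
                declared.add(tid)
            if feature != "exon":
                continue
            gid = attrs.get("gene_id", tid)
            exons.setdefault(tid, []).append((int(start) - 1, int(end)))
            meta[tid] = (chrom, strand, gid)
    models = []
    for tid, ex in exons.items():
        chrom, strand, gid = meta[tid]
        models.append(
            TranscriptModel(
                chrom=chrom,
                strand=strand,
                exons=tuple(sorted(ex)),
                transcript_id=tid,
                gene_id=gid,
            )
        )
    ann = Annotation.from_models(
        sorted(models, key=lambda m: (m.chrom, m.start, m.transcript_id))
    )
    ann.skipped = len(declared - set(exons))  # type: ignore[attr-defined]
    return ann


# ---------------------------------------------------------------------------
# SAM/BAM
# ---------------------------------------------------------------------------

class AlignmentStream:
    """Iterator over primary alignments with skip counters."""

    def __init__(self, path: str | os.PathLike, region: str | None = None):
        self.path = str(path)
        self.region = region
        self.n_unmapped = 0
        self.n_secondary = 0

    def _check_sorted(self, af: pysam.AlignmentFile) -> None:
        header = af.header.to_dict()
        so = header.get("HD", {}).get("SO")
        if so != "coordinate":
            raise ParseError(f"{self.path}: input must be coordinate-sorted (SO={so!r})")
        if "SQ" not in header or not header["SQ"]:
            raise ParseError(f"{self.path}: missing @SQ header lines")

    def __iter__(self) -> Iterator[pysam.AlignedSegment]:
        with pysam.AlignmentFile(self.path, check_sq=True) as af:
            self._check_sorted(af)
            it = af.fetch(self.region) if self.region else af
            for rec in it:
                if rec.is_unmapped:
                    self.n_unmapped += 1
                    continue
                if rec.is_secondary or rec.is_supplementary:
                    self.n_secondary += 1
                    continue
                yield rec


def read_alignments(path: str | os.PathLike, region: str | None = None) -> AlignmentStream:
    """Stream primary alignments from a coordinate-sorted SAM/BAM file.

    Secondary and supplementary records are excluded; unmapped records are
    skipped and counted on the returned stream.
    """
    return AlignmentStream(path, region=region)


def split_by_chrom(path: str | os.PathLike, n_parts: int, outdir: str | os.PathLike) -> list[Path]:
    """Split a sorted SAM/BAM into ``n_parts`` SAM files, whole chromosomes only.

    Chromosomes are assigned to parts round-robin in header order so each
    chromosome's records land wholly in one part.  Returns the part paths
    (some may hold zero records when n_parts exceeds the chromosome count).
    """
    if n_parts < 1:
        raise ValueError("n_parts must be >= 1")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with pysam.AlignmentFile(str(path), check_sq=True) as af:
        header = af.header
        refs = list(header.references)
        part_of = {ref: i % n_parts for i, ref in enumerate(refs)}
        stem = Path(path).stem
        paths = [outdir / f"{stem}_part{i}.sam" for i in range(n_parts)]
        outs = [pysam.AlignmentFile(str(p), "w", header=header) for p in paths]
        try:
            for rec in af:
                if rec.is_unmapped:
                    continue
                outs[part_of[rec.reference_name]].write(rec)
        finally:
            for o in outs:
                o.close()
    return paths


# ---------------------------------------------------------------------------
# trans_read trace files (model -> supporting read ids)
# ---------------------------------------------------------------------------

def write_trans_read(trace: dict[str, list[str]], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("transcript_id\tread_id\n")
        for tid in sorted(trace):
            for rid in sorted(trace[tid]):
                fh.write(f"{tid}\t{rid}\n")


def read_trans_read(path: str | os.PathLike) -> dict[str, list[str]]:
    trace: dict[str, list[str]] = {}
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("transcript_id"):
            raise ParseError(f"{path}: missing trans_read header")
        for line in fh:
            tid, rid = line.rstrip("\n").split("\t")
            trace.setdefault(tid, []).append(rid)
    return trace
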