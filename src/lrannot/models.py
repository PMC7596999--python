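"""Core domain objects shared by every stage of the toolkit.

The unit of work throughout is the :class:`TranscriptModel`: a strand-aware
chain of exons on one chromosome.  All coordinates are 0-based half-open
(BED convention); GTF input is converted at the parsing boundary and nowhere
else.  A splice junction (SJ) is the pair ``(end_i, start_{i+1})`` of
adjacent exons; single-exon models have an empty junction chain.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator


Exon = tuple[int, int]


@dataclass(frozen=True)
class TranscriptModel:
    """One transcript: an ordered, non-overlapping exon chain on a strand.

    Exons are genomic ``(start, end)`` intervals, 0-based half-open, sorted
    ascending regardless of strand.  5'/3' orientation is derived from
    ``strand`` where it matters (TSS/TES accessors below).
    """

    chrom: str
    strand: str
    exons: tuple[Exon, ...]
    transcript_id: str
    gene_id: str
    sources: frozenset[str] = frozenset()
    read_count: int = 0

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not self.exons:
            raise ValueError(f"{self.transcript_id}: transcript needs >=1 exon")
        exons = tuple((int(s), int(e)) for s, e in self.exons)
        object.__setattr__(self, "exons", exons)
        prev_end = None
        for s, e in exons:
            if s >= e:
                raise ValueError(f"{self.transcript_id}: empty/inverted exon ({s},{e})")
            if prev_end is not None and s < prev_end:
                raise ValueError(f"{self.transcript_id}: exons overlap or unsorted")
            prev_end = e
        if self.read_count < 0:
            raise ValueError("read_count must be non-negative")
        object.__setattr__(self, "sources", frozenset(self.sources))

    # -- span ----------------------------------------------------------
    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    # -- strand-aware ends ---------------------------------------------
    @property
    def tss(self) -> int:
        """Transcription start site (5' end), as a genomic coordinate."""
        return self.start if self.strand == "+" else self.end

    @property
    def tes(self) -> int:
        """Transcription end site (3' end), as a genomic coordinate."""
        return self.end if self.strand == "+" else self.start

    # -- junctions ------------------------------------------------------
    @property
    def junctions(self) -> tuple[tuple[int, int], ...]:
        """Splice junctions as (donor-side end, acceptor-side start) in
        genomic left-to-right order, irrespective of strand."""
        return tuple(
            (self.exons[i][1], self.exons[i + 1][0])
            for i in range(len(self.exons) - 1)
        )

    def oriented_junctions(self) -> tuple[tuple[int, int], ...]:
        """Junctions ordered 5' -> 3' along the transcript."""
        j = self.junctions
        return j if self.strand == "+" else tuple(reversed(j))

    def spliced_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    def with_ids(self, gene_id: str, transcript_id: str) -> "TranscriptModel":
        return replace(self, gene_id=gene_id, transcript_id=transcript_id)


@dataclass
class Annotation:
    """A set of transcript models plus the gene -> transcripts index."""

    models: list[TranscriptModel] = field(default_factory=list)
    loci: dict[str, list[str]] = field(default_factory=dict)

    @classmethod
    def from_models(cls, models: Iterable[TranscriptModel]) -> "Annotation":
        models = list(models)
        seen: set[str] = set()
        loci: dict[str, list[str]] = {}
        for m in models:
            if m.transcript_id in seen:
                raise ValueError(f"duplicate transcript_id {m.transcript_id!r}")
            seen.add(m.transcript_id)
            loci.setdefault(m.gene_id, []).append(m.transcript_id)
        return cls(models=models, loci=loci)

    def __len__(self) -> int:
        return len(self.models)

    def __iter__(self) -> Iterator[TranscriptModel]:
        return iter(self.models)

    def get(self, transcript_id: str) -> TranscriptModel:
        for m in self.models:
            if m.transcript_id == transcript_id:
                return m
        raise KeyError(transcript_id)

    def by_id(self) -> dict[str, TranscriptModel]:
        return {m.transcript_id: m for m in self.models}

    def sorted(self) -> "Annotation":
        """Deterministic ordering: (chrom, start, transcript_id)."""
        return Annotation.from_models(
            sorted(self.models, key=lambda m: (m.chrom, m.start, m.transcript_id))
        )


def gene_span(models: Iterable[TranscriptModel]) -> tuple[str, str, int, int]:
    """(chrom, strand, start, end) covering all models of one gene."""
    models = list(models)
    chrom = models[0].chrom
    strand = models[0].strand
    return chrom, strand, min(m.start for m in models), max(m.end for m in models)
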