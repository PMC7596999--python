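"""Mismatch-event profiling of spliced alignments, and the per-read filters.

Each mapped read becomes a :class:`MappedReadAlignment`: its exon-like
aligned blocks (N gaps are introns) plus a positioned list of mismatch
events — soft clips, insertions, deletions and substitutions.  Hard clips
are excluded throughout.  Two filters operate on the profile:

* quality filtration — alignment coverage and identity thresholds;
* local density error (LDE) — the number of mismatch bases within a fixed
  window flanking each splice junction, used to discard reads whose error
  density around junctions makes their splice calls untrustworthy.

Event positioning conventions: substitution runs are decomposed into
length-1 events so windowed counts are base-accurate; deletions occupy
``[ref_pos, ref_pos+length)``; insertions and soft clips carry all their
bases at a single anchor coordinate (left flank for insertions, the
alignment edge for clips).  "Within the window" is inclusive at a distance
exactly equal to the window, and only exonic-side bases are counted —
intron interiors are unaligned.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pysam

SOFTCLIP5 = "softclip5"
SOFTCLIP3 = "softclip3"
INSERTION = "insertion"
DELETION = "deletion"
SUBSTITUTION = "substitution"

EVENT_KINDS = (SOFTCLIP5, SOFTCLIP3, INSERTION, DELETION, SUBSTITUTION)


@dataclass(frozen=True)
class MismatchEvent:
    ref_pos: int
    kind: str
    length: int

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError("event length must be >= 1")
        if self.kind == SUBSTITUTION and self.length != 1:
            raise ValueError("substitution runs must be split into length-1 events")
        if self.kind not in EVENT_KINDS:
            raise ValueError(f"unknown event kind {self.kind!r}")


@dataclass
class MappedReadAlignment:
    read_id: str
    chrom: str
    strand: str
    blocks: tuple[tuple[int, int], ...]
    events: tuple[MismatchEvent, ...]
    read_length: int
    mapped_span: int
    identity: float
    coverage: float

    @property
    def start(self) -> int:
        return self.blocks[0][0]

    @property
    def end(self) -> int:
        return self.blocks[-1][1]

    @property
    def junctions(self) -> tuple[tuple[int, int], ...]:
        return tuple(
            (self.blocks[i][1], self.blocks[i + 1][0])
            for i in range(len(self.blocks) - 1)
        )


@dataclass(frozen=True)
class QualityThresholds:
    min_coverage: float = 0.0
    min_identity: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.min_coverage <= 1.0 and 0.0 <= self.min_identity <= 1.0):
            raise ValueError("thresholds must lie in [0, 1]")


class GenomeAccessor:
    """Minimal genome interface: ``fetch(chrom, start, end) -> str`` (upper)."""

    def __init__(self, fasta):
        # accepts a pyfaidx.Fasta or a plain dict of chrom -> sequence
        self._fasta = fasta

    def fetch(self, chrom: str, start: int, end: int) -> str:
        start = max(start, 0)
        if isinstance(self._fasta, dict):
            return self._fasta[chrom][start:end].upper()
        return str(self._fasta[chrom][start:end]).upper()

    def __contains__(self, chrom: str) -> bool:
        if isinstance(self._fasta, dict):
            return chrom in self._fasta
        return chrom in self._fasta.keys()

    def length(self, chrom: str) -> int:
        return len(self._fasta[chrom])


def profile_alignment(rec: pysam.AlignedSegment, genome: GenomeAccessor) -> MappedReadAlignment:
    """Build the mismatch-event profile of one primary spliced alignment.

    Substitutions are called by comparing the read sequence against the
    genome base-by-base over aligned blocks (falling back to the MD tag when
    SEQ is absent).  The mismatch rate is the total event bases (hard clips
    excluded) over the read length; identity is ``1 - mismatch_rate``.
    """
    if rec.cigartuples is None:
        raise ValueError(f"{rec.query_name}: missing CIGAR")
    chrom = rec.reference_name
    if chrom not in genome:
        raise ValueError(f"{rec.query_name}: chrom {chrom!r} absent from genome")
    strand = "-" if rec.is_reverse else "+"

    events: list[MismatchEvent] = []
    blocks: list[tuple[int, int]] = []
    ref_pos = rec.reference_start
    query_pos = 0
    block_start: int | None = None
    seq = rec.query_sequence

    cig = rec.cigartuples
    n_ops = len(cig)
    for i, (op, length) in enumerate(cig):
        if op == 4:  # S
            leading = i == 0 or (i == 1 and cig[0][0] == 5)
            anchor = rec.reference_start if leading else ref_pos
            if strand == "+":
                kind = SOFTCLIP5 if leading else SOFTCLIP3
            else:
                kind = SOFTCLIP3 if leading else SOFTCLIP5
            events.append(MismatchEvent(anchor, kind, length))
            query_pos += length
        elif op == 5:  # H — excluded entirely
            continue
        elif op == 1:  # I, anchored at left flank
            events.append(MismatchEvent(ref_pos, INSERTION, length))
            query_pos += length
        elif op == 2:  # D
            events.append(MismatchEvent(ref_pos, DELETION, length))
            ref_pos += length
        elif op == 3:  # N — intron: close the current block
            if block_start is not None:
                blocks.append((block_start, ref_pos))
                block_start = None
            ref_pos += length
        elif op in (0, 7, 8):  # M / = / X
            if block_start is None:
                block_start = ref_pos
            if op == 7:
                pass  # sequence-match op: no substitutions here
            elif seq is not None:
                ref_seq = genome.fetch(chrom, ref_pos, ref_pos + length)
                read_seq = seq[query_pos : query_pos + length].upper()
                for k in range(length):
                    if k < len(ref_seq) and read_seq[k] != ref_seq[k]:
                        events.append(MismatchEvent(ref_pos + k, SUBSTITUTION, 1))
            elif op == 8:
                for k in range(length):
                    events.append(MismatchEvent(ref_pos + k, SUBSTITUTION, 1))
            else:
                raise ValueError(
                    f"{rec.query_name}: cannot call substitutions without SEQ"
                )
            ref_pos += length
            query_pos += length
        else:
            raise ValueError(f"{rec.query_name}: unsupported CIGAR op {op}")
    if block_start is not None:
        blocks.append((block_start, ref_pos))

    # merge blocks separated only by D/I (which do not open a new exon)
    merged: list[tuple[int, int]] = []
    for b in blocks:
        if merged and b[0] <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], b[1]))
        else:
            merged.append(b)

    read_length = rec.infer_query_length() or query_pos
    clip_bases = sum(e.length for e in events if e.kind in (SOFTCLIP5, SOFTCLIP3))
    mismatch_bases = sum(e.length for e in events)
    mapped_span = read_length - clip_bases
    coverage = mapped_span / read_length if read_length else 0.0
    identity = max(0.0, 1.0 - mismatch_bases / read_length) if read_length else 0.0

    return MappedReadAlignment(
        read_id=rec.query_name,
        chrom=chrom,
        strand=strand,
        blocks=tuple(merged),
        events=tuple(events),
        read_length=read_length,
        mapped_span=mapped_span,
        identity=identity,
        coverage=coverage,
    )


def pass_quality(aln: MappedReadAlignment, thresholds: QualityThresholds) -> bool:
    """True iff both alignment coverage and identity meet their thresholds."""
    return aln.coverage >= thresholds.min_coverage and aln.identity >= thresholds.min_identity


def _event_bases_in(events: Iterable[MismatchEvent], lo: int, hi: int) -> int:
    """Mismatch bases attributable to [lo, hi) on the reference."""
    total = 0
    for e in events:
        if e.kind in (DELETION, SUBSTITUTION):
            total += max(0, min(e.ref_pos + e.length, hi) - max(e.ref_pos, lo))
        else:  # insertion / clip: all bases at the anchor
            if lo <= e.ref_pos < hi:
                total += e.length
    return total


def sj_error_profile(
    aln: MappedReadAlignment, window: int
) -> list[tuple[int, int]]:
    """Per-junction (left, right) mismatch-base counts within ``window``.

    Left counts cover the exonic bases immediately 5' (genomic left) of the
    donor boundary, right counts those immediately 3' (genomic right) of the
    acceptor boundary.  Single-exon alignments return an empty list.
    """
    out = []
    for donor_end, acceptor_start in aln.junctions:
        left = _event_bases_in(aln.events, donor_end - window, donor_end)
        right = _event_bases_in(aln.events, acceptor_start, acceptor_start + window)
        out.append((left, right))
    return out


def pass_lde(aln: MappedReadAlignment, window: int, max_mismatch: int) -> bool:
    """Local-density-error filter: every junction's flanking mismatch count
    must be at most ``max_mismatch``.  Single-exon reads vacuously pass."""
    return all(
        left + right <= max_mismatch for left, right in sj_error_profile(aln, window)
    )


def mismatch_summary(alns: Sequence[MappedReadAlignment]) -> dict[str, float]:
    """Mean per-read mismatch rate by event kind, plus the overall mean.

    Rates are fractions of read length; multiply by 100 for the percent
    scale usually reported.
    """
    rates = {kind: 0.0 for kind in EVENT_KINDS}
    overall = 0.0
    n = len(alns)
    if n == 0:
        return {**rates, "overall": 0.0}
    for aln in alns:
        by_kind = {kind: 0 for kind in EVENT_KINDS}
        for e in aln.events:
            by_kind[e.kind] += e.length
        for kind in EVENT_KINDS:
            rates[kind] += by_kind[kind] / aln.read_length / n
        overall += sum(by_kind.values()) / aln.read_length / n
    return {**rates, "overall": overall}


def write_read_report(
    alns: Sequence[MappedReadAlignment],
    decisions: dict[str, tuple[bool, str]],
    path,
) -> None:
    """Per-read report TSV: coordinates, quality metrics, per-kind mismatch
    counts and the accept/discard decision with its reason."""
    cols = [
        "read_id", "chrom", "start", "end", "strand", "coverage", "identity",
        *EVENT_KINDS, "decision", "reason",
    ]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for aln in alns:
            by_kind = {kind: 0 for kind in EVENT_KINDS}
            for e in aln.events:
                by_kind[e.kind] += e.length
            ok, reason = decisions.get(aln.read_id, (True, ""))
            fh.write(
                "\t".join(
                    [
                        aln.read_id, aln.chrom, str(aln.start), str(aln.end),
                        aln.strand, f"{aln.coverage:.4f}", f"{aln.identity:.4f}",
                        *(str(by_kind[k]) for k in EVENT_KINDS),
                        "accept" if ok else "discard", reason,
                    ]
                )
                + "\n"
            )
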