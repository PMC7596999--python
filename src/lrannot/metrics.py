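"""Diagnostic statistics: degradation signature, splice-junction wobble
against a reference, and read-jumble (model-change) detection.

The Degradation Signature (DegSig) estimates the fraction of reads that
came from 5'-degraded RNA.  Collapsing the same reads under capped and
no_cap modes yields CT and NT multi-exon transcript models (counted only in
genes with more than one supporting read); truncation-derived models merge
away under no_cap, so

    DegSig = (CT - NT) / CT

is the proportion of models explained by 5' truncation.  Alternative
transcription start sites and incomplete first-strand synthesis also
produce 5' variability, so the statistic is an upper-bound style proxy, not
a direct measurement.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable

from .models import Annotation, TranscriptModel
from .support import ReadSupport


@dataclass(frozen=True)
class DegSigResult:
    CT: int
    NT: int

    @property
    def degsig(self) -> float | None:
        """(CT - NT)/CT as a fraction; None when CT == 0."""
        if self.CT == 0:
            return None
        return (self.CT - self.NT) / self.CT

    @property
    def percent(self) -> float | None:
        d = self.degsig
        return None if d is None else round(100.0 * d, 1)


def _count_multiexon_multiread(annotation: Annotation, support: ReadSupport) -> int:
    gene_support = support.gene_support(annotation)
    gene_reads = {g: len({rid for _, rid in pairs}) for g, pairs in gene_support.items()}
    return sum(
        1
        for m in annotation
        if m.n_exons > 1 and gene_reads.get(m.gene_id, 0) > 1
    )


def degradation_signature(
    capped: tuple[Annotation, ReadSupport],
    nocap: tuple[Annotation, ReadSupport],
) -> DegSigResult:
    """DegSig from a capped and a no_cap collapse of the same reads.

    CT (NT) is the number of multi-exon transcript models from genes with
    more than one supporting read in the capped (no_cap) run.  The two runs
    must cover the same reads; a mismatch is warned about with the size of
    the symmetric difference.
    """
    cap_ann, cap_rs = capped
    no_ann, no_rs = nocap
    cap_reads = {rid for pairs in cap_rs.transcripts.values() for _, rid in pairs}
    no_reads = {rid for pairs in no_rs.transcripts.values() for _, rid in pairs}
    diff = len(cap_reads ^ no_reads)
    if diff:
        warnings.warn(
            f"capped and no_cap runs cover different reads ({diff} in symmetric difference)",
            stacklevel=2,
        )
    return DegSigResult(
        CT=_count_multiexon_multiread(cap_ann, cap_rs),
        NT=_count_multiexon_multiread(no_ann, no_rs),
    )


# ---------------------------------------------------------------------------
# Splice-junction wobble against a reference annotation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WobbleRecord:
    query_id: str
    ref_id: str
    offsets: tuple[int, ...]  # signed, query - reference, donor & acceptor per SJ

    @property
    def mean_abs(self) -> float:
        return sum(abs(o) for o in self.offsets) / len(self.offsets) if self.offsets else 0.0


def sj_wobble(
    query: Annotation,
    reference: Annotation,
    max_wobble: int = 30,
    ends_window: int = 300,
) -> list[WobbleRecord]:
    """Per-junction signed offsets of query models against matching
    reference models.

    A query transcript matches a reference transcript when both have the
    same junction count, every donor/acceptor differs by at most
    ``max_wobble`` and the transcript ends by at most ``ends_window``.
    Offsets are reported per junction boundary (query - reference);
    transcript start/end wobble is excluded, so single-exon pairs produce
    an empty offset tuple.
    """
    out: list[WobbleRecord] = []
    ref_sorted = sorted(reference, key=lambda m: (m.chrom, m.start))
    for q in query:
        for r in ref_sorted:
            if q.chrom != r.chrom or q.strand != r.strand or q.n_exons != r.n_exons:
                continue
            if abs(q.start - r.start) > ends_window or abs(q.end - r.end) > ends_window:
                continue
            offsets: list[int] = []
            ok = True
            for (qd, qa), (rd, ra) in zip(q.junctions, r.junctions):
                if abs(qd - rd) > max_wobble or abs(qa - ra) > max_wobble:
                    ok = False
                    break
                offsets.extend([qd - rd, qa - ra])
            if ok:
                out.append(WobbleRecord(q.transcript_id, r.transcript_id, tuple(offsets)))
    return out


def mean_sj_wobble(records: Iterable[WobbleRecord]) -> float:
    """Mean |offset| over all junction boundaries of all matched pairs."""
    offsets = [abs(o) for rec in records for o in rec.offsets]
    return sum(offsets) / len(offsets) if offsets else 0.0


# ---------------------------------------------------------------------------
# Read jumble detection
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class JumbleEvent:
    read_id: str
    model_before: str
    model_after: str
    gene_before: str
    gene_after: str
    level: str  # "gene" | "transcript"


def find_model_changes(merged: Annotation, support: ReadSupport) -> list[JumbleEvent]:
    """Reads whose model assignment differs between the two merged pipelines.

    ``merged`` must be the merge of two pipeline annotations with read
    support traced from both.  Any read supporting more than one merged
    transcript is a jumble event; the event is gene-level when the two
    models belong to different genes.
    """
    gene_of = {m.transcript_id: m.gene_id for m in merged}
    by_read: dict[str, set[str]] = {}
    for tid, pairs in support.transcripts.items():
        if tid not in gene_of:
            continue
        for _src, rid in pairs:
            by_read.setdefault(rid, set()).add(tid)
    events: list[JumbleEvent] = []
    for rid in sorted(by_read):
        tids = sorted(by_read[rid])
        if len(tids) < 2:
            continue
        genes = {gene_of[t] for t in tids}
        before, after = tids[0], tids[1]
        events.append(
            JumbleEvent(
                read_id=rid,
                model_before=before,
                model_after=after,
                gene_before=gene_of[before],
                gene_after=gene_of[after],
                level="gene" if len(genes) > 1 else "transcript",
            )
        )
    return events


def jumble_summary(events: Iterable[JumbleEvent]) -> dict[str, int]:
    events = list(events)
    return {
        "gene": sum(1 for e in events if e.level == "gene"),
        "transcript": sum(1 for e in events if e.level == "transcript"),
        "total": len(events),
    }
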