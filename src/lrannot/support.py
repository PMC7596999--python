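"""Read-support tracing and support/fragment/guided filtering.

Every collapse run emits a trace (model id -> supporting read ids) and every
merge emits a report (final id -> contributing (source, model id) pairs).
:func:`read_support_levels` composes these transitively so a final merged
model can always be traced back to the original read ids, however many merge
steps intervened.  The filters below consume that support information or the
annotation structure alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Sequence

from .collapse import WobbleThresholds, match_nocap
from .merge import MergeReport, MergeSourceSpec, merge
from .models import Annotation, TranscriptModel


@dataclass
class ReadSupport:
    """Per-transcript and per-gene sets of (source label, read id)."""

    transcripts: dict[str, set[tuple[str, str]]] = field(default_factory=dict)

    def gene_support(self, annotation: Annotation) -> dict[str, set[tuple[str, str]]]:
        out: dict[str, set[tuple[str, str]]] = {}
        for gid, tids in annotation.loci.items():
            out[gid] = set().union(*(self.transcripts.get(t, set()) for t in tids))
        return out

    def read_count(self, transcript_id: str) -> int:
        return len({rid for _, rid in self.transcripts.get(transcript_id, set())})

    def source_count(self, transcript_id: str) -> int:
        return len({src for src, _ in self.transcripts.get(transcript_id, set())})


def read_support_levels(
    traces: Mapping[str, Mapping[str, Iterable[str]]],
    merge_reports: Sequence[tuple[str, Mapping[str, Sequence[tuple[str, str]]]]] = (),
) -> ReadSupport:
    """Resolve final model ids to original read ids.

    ``traces`` maps a collapse label to its model->reads mapping.  Each
    entry of ``merge_reports`` is ``(label, final_id -> [(source, member_id),
    ...])``; sources may be collapse labels or earlier merge labels, so
    support composes through arbitrarily many merge steps.  The support of
    the *last* report (or the union of the traces when none are given) is
    returned.  A contributor that resolves to no known trace raises.
    """
    resolved: dict[str, dict[str, set[tuple[str, str]]]] = {}
    for label, trace in traces.items():
        resolved[label] = {
            mid: {(label, rid) for rid in rids} for mid, rids in trace.items()
        }
    last_label = None
    for label, report in merge_reports:
        layer: dict[str, set[tuple[str, str]]] = {}
        for final_id, contributors in report.items():
            bucket: set[tuple[str, str]] = set()
            for src, member_id in contributors:
                if src not in resolved:
                    raise ValueError(f"unknown contributor source {src!r} for {final_id}")
                if member_id not in resolved[src]:
                    raise ValueError(
                        f"dangling contributor id {src}:{member_id} for {final_id}"
                    )
                bucket |= resolved[src][member_id]
            layer[final_id] = bucket
        resolved[label] = layer
        last_label = label
    if last_label is not None:
        return ReadSupport(transcripts=dict(resolved[last_label]))
    union: dict[str, set[tuple[str, str]]] = {}
    for label in traces:
        for mid, pairs in resolved[label].items():
            union.setdefault(mid, set()).update(pairs)
    return ReadSupport(transcripts=union)


def write_read_support(support: ReadSupport, path) -> None:
    with open(path, "w") as fh:
        fh.write("transcript_id\tsource\tread_id\n")
        for tid in sorted(support.transcripts):
            for src, rid in sorted(support.transcripts[tid]):
                fh.write(f"{tid}\t{src}\t{rid}\n")


def read_read_support(path) -> ReadSupport:
    transcripts: dict[str, set[tuple[str, str]]] = {}
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("transcript_id"):
            raise ValueError(f"{path}: missing read-support header")
        for line in fh:
            tid, src, rid = line.rstrip("\n").split("\t")
            transcripts.setdefault(tid, set()).add((src, rid))
    return ReadSupport(transcripts=transcripts)


def support_from_merge(report: MergeReport, traces: Mapping[str, Mapping[str, Iterable[str]]]) -> ReadSupport:
    """Convenience: read support of one merge over its collapse traces."""
    return read_support_levels(traces, [("merged", report.transcripts)])


# ---------------------------------------------------------------------------
# Fragment removal
# ---------------------------------------------------------------------------

def _junctions_within(
    frag: tuple[tuple[int, int], ...],
    full: tuple[tuple[int, int], ...],
    m: int,
) -> bool:
    """Is ``frag`` a contiguous subchain of ``full`` within wobble m?"""
    k, n = len(frag), len(full)
    for off in range(n - k + 1):
        if all(
            abs(frag[i][0] - full[off + i][0]) <= m
            and abs(frag[i][1] - full[off + i][1]) <= m
            for i in range(k)
        ):
            return True
    return False


def is_fragment_of(candidate: TranscriptModel, other: TranscriptModel, m: int) -> bool:
    """True iff ``candidate`` is a fragment of ``other``: its full junction
    chain is a contiguous subchain of the other's (within ``m``) and the
    other extends strictly beyond it on BOTH genomic ends.  A single-exon
    candidate is a fragment when it sits strictly inside one exon of the
    other model."""
    if candidate.chrom != other.chrom or candidate.strand != other.strand:
        return False
    if candidate.n_exons == 1:
        s, e = candidate.exons[0]
        return any(S < s and e < E for S, E in other.exons)
    if other.n_exons <= candidate.n_exons:
        return False
    if not (other.start < candidate.start and candidate.end < other.end):
        return False
    return _junctions_within(candidate.junctions, other.junctions, m)


def remove_fragments(annotation: Annotation, m: int = 0) -> Annotation:
    """Drop transcript models that are fragments of a longer model."""
    models = list(annotation)
    keep = [
        cand
        for cand in models
        if not any(
            other is not cand and is_fragment_of(cand, other, m) for other in models
        )
    ]
    return Annotation.from_models(keep)


# ---------------------------------------------------------------------------
# Support-based filtering
# ---------------------------------------------------------------------------

def filter_by_support(
    annotation: Annotation,
    support: ReadSupport,
    level: Literal["transcript", "gene"] = "transcript",
    min_count: int = 1,
    unit: Literal["reads", "sources"] = "reads",
) -> Annotation:
    """Keep items with at least ``min_count`` distinct reads (or distinct
    source labels).  Gene-level removal drops all the gene's transcripts."""

    def count(pairs: set[tuple[str, str]]) -> int:
        if unit == "reads":
            return len({rid for _, rid in pairs})
        return len({src for src, _ in pairs})

    if level == "transcript":
        keep_ids = {
            tid
            for tid in (m.transcript_id for m in annotation)
            if count(support.transcripts.get(tid, set())) >= min_count
        }
    else:
        gene_support = support.gene_support(annotation)
        keep_genes = {g for g, pairs in gene_support.items() if count(pairs) >= min_count}
        keep_ids = {
            m.transcript_id for m in annotation if m.gene_id in keep_genes
        }
    return Annotation.from_models([m for m in annotation if m.transcript_id in keep_ids])


# ---------------------------------------------------------------------------
# Guided (reference-matched) filtering
# ---------------------------------------------------------------------------

def guided_filter(
    long_read: Annotation, reference: Annotation, w: WobbleThresholds
) -> tuple[Annotation, MergeReport]:
    """Keep only long-read models matching the reference annotation and
    adopt the reference coordinates.

    Implemented as a merge of the long-read annotation (no_cap, priority
    2,2,2) with the reference (capped, priority 1,1,1), keeping merged
    transcripts supported by both sources.
    """
    merged, report = merge(
        [
            MergeSourceSpec(None, "longread", mode="no_cap", priority=(2, 2, 2), annotation=long_read),
            MergeSourceSpec(None, "reference", mode="capped", priority=(1, 1, 1), annotation=reference),
        ],
        w,
    )
    keep = [
        m
        for m in merged
        if len({lbl for lbl, _ in report.transcripts[m.transcript_id]}) >= 2
    ]
    kept = Annotation.from_models(keep)
    report.transcripts = {m.transcript_id: report.transcripts[m.transcript_id] for m in keep}
    return kept, report
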