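"""Merge transcriptome annotations into a non-redundant set.

Each input annotation carries its own collapse mode and a feature-priority
triple (TSS, SJ, TES; 1 = highest).  Models are grouped with the same
pairwise wobble matching as read collapsing; a mixed pair (one capped, one
no_cap source) is compared under no_cap, which is what lets 5'-truncated
long-read models absorb into a full-length reference model.  Within each
merged group the splice junctions are taken from the highest-SJ-priority
source present, and the transcript ends from the highest TSS/TES-priority
sources — so a reference annotation given priority (1,1,1) donates its
coordinates to every model it matches.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

from .collapse import (
    Chain,
    WobbleThresholds,
    _UnionFind,
    match_capped,
    match_nocap,
)
from .models import Annotation, TranscriptModel


@dataclass
class MergeSourceSpec:
    path: str | None
    label: str
    mode: Literal["capped", "no_cap"] = "capped"
    priority: tuple[int, int, int] = (1, 1, 1)  # (tss, sj, tes), 1 = highest
    annotation: Annotation | None = None

    def load(self) -> Annotation:
        if self.annotation is not None:
            return self.annotation
        from . import io

        if self.path is None:
            raise ValueError(f"source {self.label!r}: neither path nor annotation given")
        if str(self.path).endswith((".gtf", ".gtf.gz")):
            return io.read_gtf(self.path)
        return io.read_bed12(self.path)


@dataclass
class MergeReport:
    """Trace of how each final model was assembled."""

    # final transcript id -> [(source label, source transcript id), ...]
    transcripts: dict[str, list[tuple[str, str]]] = field(default_factory=dict)
    # final gene id -> contributing source labels
    genes: dict[str, set[str]] = field(default_factory=dict)
    # final transcript id -> {(label, source tid): [signed boundary offsets]}
    wobble: dict[str, dict[tuple[str, str], list[int]]] = field(default_factory=dict)


@dataclass
class _Member:
    label: str
    model: TranscriptModel
    mode: str
    priority: tuple[int, int, int]


def _pair_match(a: _Member, b: _Member, w: WobbleThresholds) -> bool:
    # a mixed pair is compared under no_cap (truncation-tolerant)
    strand = a.model.strand
    if a.mode == "no_cap" or b.mode == "no_cap":
        return match_nocap(a.model.exons, b.model.exons, strand, w)
    return match_capped(a.model.exons, b.model.exons, strand, w)


def _representative(members: Sequence[_Member]) -> _Member:
    def key(m: _Member):
        mod = m.model
        tss = mod.start if mod.strand == "+" else -mod.end
        return (-(mod.n_exons - 1), -(mod.end - mod.start), tss, m.label, mod.transcript_id)

    return min(members, key=key)


def _slot_of(j: int, n_member: int, n_rep: int, strand: str) -> int:
    if strand == "+":
        return n_rep - n_member + j
    return j


def _merge_component(members: list[_Member], w: WobbleThresholds) -> tuple[Chain, list[tuple[str, str]]]:
    """Resolve one matched group to a final exon chain."""
    strand = members[0].model.strand
    rep = _representative(members)
    n_rep = rep.model.n_exons - 1

    # --- splice junctions by SJ priority ---
    slots: list[dict[tuple[int, int], list[_Member]]] = [dict() for _ in range(n_rep)]
    for mem in members:
        n_mem = mem.model.n_exons - 1
        for j, junction in enumerate(mem.model.junctions):
            slot = _slot_of(j, n_mem, n_rep, strand)
            if 0 <= slot < n_rep:
                slots[slot].setdefault(junction, []).append(mem)
    junctions: list[tuple[int, int]] = []
    for cand in slots:
        if not cand:
            continue
        best_rank = min(min(m.priority[1] for m in mems) for mems in cand.values())

        def key(item):
            junction, mems = item
            ranks = [m.priority[1] for m in mems]
            return (min(ranks), -len(mems), junction)

        junctions.append(min(cand.items(), key=key)[0])

    # --- transcript ends by TSS/TES priority, extremes within the pool ---
    tss_rank = min(m.priority[0] for m in members)
    tes_rank = min(m.priority[2] for m in members)
    tss_pool = [m.model for m in members if m.priority[0] == tss_rank]
    tes_pool = [m.model for m in members if m.priority[2] == tes_rank]
    if strand == "+":
        left = min(m.start for m in tss_pool)
        right = max(m.end for m in tes_pool)
    else:
        left = min(m.start for m in tes_pool)
        right = max(m.end for m in tss_pool)

    # drop junction slots outside the chosen span (a low-priority member may
    # extend 5' of the priority source's start)
    usable = sorted(j for j in junctions if left < j[0] and j[1] < right)
    bounds = [left]
    for donor, acceptor in usable:
        bounds.extend([donor, acceptor])
    bounds.append(right)
    exons = tuple((bounds[i], bounds[i + 1]) for i in range(0, len(bounds), 2))
    if not (
        all(s < e for s, e in exons)
        and all(exons[i][1] <= exons[i + 1][0] for i in range(len(exons) - 1))
    ):
        exons = rep.model.exons
    contributors = sorted((m.label, m.model.transcript_id) for m in members)
    return exons, contributors


def merge(
    sources: Sequence[MergeSourceSpec], w: WobbleThresholds
) -> tuple[Annotation, MergeReport]:
    """Combine annotations into a non-redundant set with trace reports."""
    if not sources:
        raise ValueError("merge needs at least one source")
    labels = [s.label for s in sources]
    if len(set(labels)) != len(labels):
        raise ValueError("source labels must be unique")

    members: list[_Member] = []
    for spec in sources:
        ann = spec.load()
        members.extend(
            _Member(spec.label, m, spec.mode, tuple(spec.priority)) for m in ann
        )

    # group per chrom/strand via overlap sweep + union-find
    by_key: dict[tuple[str, str], list[_Member]] = {}
    for mem in members:
        by_key.setdefault((mem.model.chrom, mem.model.strand), []).append(mem)
    components: list[list[_Member]] = []
    for key in sorted(by_key):
        items = sorted(
            by_key[key], key=lambda m: (m.model.start, m.model.end, m.label, m.model.transcript_id)
        )
        uf = _UnionFind(len(items))
        for i, a in enumerate(items):
            for j in range(i + 1, len(items)):
                b = items[j]
                if b.model.start >= a.model.end:
                    break
                if _pair_match(a, b, w):
                    uf.union(i, j)
        comp: dict[int, list[_Member]] = {}
        for i, m in enumerate(items):
            comp.setdefault(uf.find(i), []).append(m)
        for root in sorted(comp):
            components.append(comp[root])

    resolved = []
    for comp_members in components:
        exons, contributors = _merge_component(comp_members, w)
        resolved.append((comp_members, exons, contributors))

    # loci by same-strand >=1bp overlap of merged spans
    loci: list[list[int]] = []
    by_cs: dict[tuple[str, str], list[int]] = {}
    for idx, (mems, exons, _) in enumerate(resolved):
        key = (mems[0].model.chrom, mems[0].model.strand)
        by_cs.setdefault(key, []).append(idx)
    for key in sorted(by_cs):
        idxs = sorted(by_cs[key], key=lambda i: (resolved[i][1][0][0], resolved[i][1][-1][1]))
        current: list[int] = []
        cur_end = -1
        for i in idxs:
            s, e = resolved[i][1][0][0], resolved[i][1][-1][1]
            if current and s >= cur_end:
                loci.append(current)
                current = []
                cur_end = -1
            current.append(i)
            cur_end = max(cur_end, e)
        if current:
            loci.append(current)
    loci.sort(
        key=lambda L: (
            resolved[L[0]][0][0].model.chrom,
            min(resolved[i][1][0][0] for i in L),
            resolved[L[0]][0][0].model.strand,
        )
    )

    models: list[TranscriptModel] = []
    report = MergeReport()
    for gi, locus in enumerate(loci, start=1):
        gene_id = f"G{gi}"
        ordered = sorted(
            locus,
            key=lambda i: (-len(resolved[i][2]), resolved[i][1][0][0], resolved[i][1][-1][1]),
        )
        gene_labels: set[str] = set()
        for ti, idx in enumerate(ordered, start=1):
            mems, exons, contributors = resolved[idx]
            tid = f"{gene_id}.{ti}"
            model = TranscriptModel(
                chrom=mems[0].model.chrom,
                strand=mems[0].model.strand,
                exons=exons,
                transcript_id=tid,
                gene_id=gene_id,
                sources=frozenset(lbl for lbl, _ in contributors),
                read_count=len(contributors),
            )
            models.append(model)
            report.transcripts[tid] = contributors
            gene_labels.update(lbl for lbl, _ in contributors)
            report.wobble[tid] = _wobble_offsets(model, mems)
        report.genes[gene_id] = gene_labels

    return Annotation.from_models(models), report


def _wobble_offsets(final: TranscriptModel, members: list[_Member]) -> dict[tuple[str, str], list[int]]:
    """Signed offsets (final - contributor) per boundary each member shares."""
    out: dict[tuple[str, str], list[int]] = {}
    n_final = final.n_exons - 1
    for mem in members:
        offs: list[int] = []
        n_mem = mem.model.n_exons - 1
        for j, (donor, acceptor) in enumerate(mem.model.junctions):
            slot = _slot_of(j, n_mem, n_final, final.strand)
            if 0 <= slot < n_final:
                fd, fa = final.junctions[slot]
                offs.extend([fd - donor, fa - acceptor])
        offs.append(final.start - mem.model.start)
        offs.append(final.end - mem.model.end)
        out[(mem.label, mem.model.transcript_id)] = offs
    return out


# ---------------------------------------------------------------------------
# Annotation comparison helpers
# ---------------------------------------------------------------------------

def loci_overlap(a: Annotation, b: Annotation) -> dict[str, list[str]]:
    """For each gene of ``b``, the genes of ``a`` sharing >=1 bp same-strand
    span overlap.  Many-to-one relations are preserved."""
    from .models import gene_span

    a_by_gene = {}
    for gid, tids in a.loci.items():
        models = [a.get(t) for t in tids]
        a_by_gene[gid] = gene_span(models)
    out: dict[str, list[str]] = {}
    for gid_b, tids in b.loci.items():
        chrom_b, strand_b, s_b, e_b = gene_span([b.get(t) for t in tids])
        hits = [
            gid_a
            for gid_a, (chrom_a, strand_a, s_a, e_a) in a_by_gene.items()
            if chrom_a == chrom_b and strand_a == strand_b and s_a < e_b and s_b < e_a
        ]
        out[gid_b] = sorted(hits)
    return out


@dataclass(frozen=True)
class ThreePrimeMatch:
    a_id: str
    b_id: str
    classification: str  # a_longer_5prime | b_longer_5prime | equal
    extra_5prime_exons: bool


def three_prime_match_compare(
    a: Annotation, b: Annotation, w: WobbleThresholds
) -> list[ThreePrimeMatch]:
    """Pairs with matching 3' exon-intron structure, classified by which
    annotation carries the longer 5' representation.

    A pair qualifies when one model's junction chain is a 3'-terminal
    suffix of the other's (within ``m``) and the 3' ends agree within
    ``z`` — the no_cap match.  The member with more exons (or, at equal
    exon counts, the more-5' start) is the longer one; the extra-exon flag
    marks pairs where the longer member has additional 5' exons.
    """
    out: list[ThreePrimeMatch] = []
    for ma in a:
        for mb in b:
            if ma.chrom != mb.chrom or ma.strand != mb.strand:
                continue
            if not match_nocap(ma.exons, mb.exons, ma.strand, w):
                continue
            if ma.n_exons != mb.n_exons:
                longer_is_a = ma.n_exons > mb.n_exons
                cls = "a_longer_5prime" if longer_is_a else "b_longer_5prime"
                out.append(ThreePrimeMatch(ma.transcript_id, mb.transcript_id, cls, True))
                continue
            # equal exon counts: compare 5' extent strand-aware
            if ma.tss == mb.tss:
                cls = "equal"
            elif ma.strand == "+":
                cls = "a_longer_5prime" if ma.tss < mb.tss else "b_longer_5prime"
            else:
                cls = "a_longer_5prime" if ma.tss > mb.tss else "b_longer_5prime"
            out.append(ThreePrimeMatch(ma.transcript_id, mb.transcript_id, cls, False))
    return out
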