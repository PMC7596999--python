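"""Collapse genome-mapped long reads into non-redundant transcript models.

Reads that pass the quality and local-density-error filters are grouped by
exon-intron structure under *wobble* matching: two chains match when every
compared boundary differs by at most the relevant wobble threshold
(``a`` at the 5' start, ``m`` at splice junctions, ``z`` at the 3' end; all
inclusive).  Matching is pairwise and grouping takes the transitive closure
of the match relation, so *wobble walking* — chains of within-threshold
boundary shifts whose extremes exceed the threshold — is permitted by
construction.

Two modes exist:

* ``capped``  — grouped reads must have the same exon count and all
  boundaries must match; appropriate for 5'-cap-selected libraries.
* ``no_cap``  — a 5'-truncated read merges into a longer model when its
  whole splice-junction chain matches a 3'-terminal suffix of the longer
  model's chain and the 3' ends agree; appropriate when RNA degradation
  produces 5'-incomplete reads.

Each group becomes one transcript model: splice junctions are chosen per
intron by ranking candidate coordinates on flanking mismatch evidence (or
raw read coverage with ranking off), and the model span takes the extreme
5'-most / 3'-most member ends.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

from .models import Annotation, TranscriptModel
from .profile import (
    GenomeAccessor,
    MappedReadAlignment,
    MismatchEvent,
    QualityThresholds,
    pass_lde,
    pass_quality,
    sj_error_profile,
    write_read_report,
)

Chain = tuple[tuple[int, int], ...]


@dataclass(frozen=True)
class WobbleThresholds:
    """Maximum allowed boundary differences, in bases (inclusive)."""

    a: int = 100  # 5' transcript start
    m: int = 10   # splice-junction donors/acceptors
    z: int = 100  # 3' transcript end

    def __post_init__(self) -> None:
        if min(self.a, self.m, self.z) < 0:
            raise ValueError("wobble thresholds must be >= 0")


@dataclass(frozen=True)
class CollapseConfig:
    mode: Literal["capped", "no_cap"] = "no_cap"
    wobble: WobbleThresholds = WobbleThresholds()
    lde_window: int = 20
    lde_max: int | None = 5
    quality: QualityThresholds = QualityThresholds()
    sj_ranking: bool = True
    sj_window: int = 20
    polya_window: int = 20
    polya_fraction: float = 0.7

    def __post_init__(self) -> None:
        if self.mode not in ("capped", "no_cap"):
            raise ValueError(f"unknown collapse mode {self.mode!r}")
        if not 0.0 <= self.polya_fraction <= 1.0:
            raise ValueError("polya_fraction must lie in [0, 1]")


# ---------------------------------------------------------------------------
# Pairwise chain matching
# ---------------------------------------------------------------------------

def _spans_overlap(x: Chain, y: Chain) -> bool:
    return x[0][0] < y[-1][1] and y[0][0] < x[-1][1]


def match_capped(x: Chain, y: Chain, strand: str, w: WobbleThresholds) -> bool:
    """Same exon count, all boundaries within wobble (a/m/z by position)."""
    if len(x) != len(y):
        return False
    if not _spans_overlap(x, y):
        return False
    # genomic-left span boundary is the 5' end on +, the 3' end on -
    left_tol, right_tol = (w.a, w.z) if strand == "+" else (w.z, w.a)
    if abs(x[0][0] - y[0][0]) > left_tol:
        return False
    if abs(x[-1][1] - y[-1][1]) > right_tol:
        return False
    for i in range(len(x) - 1):
        if abs(x[i][1] - y[i][1]) > w.m:
            return False
        if abs(x[i + 1][0] - y[i + 1][0]) > w.m:
            return False
    return True


def match_nocap(x: Chain, y: Chain, strand: str, w: WobbleThresholds) -> bool:
    """5'-truncation-tolerant match.

    The shorter chain's full junction chain must match (within ``m``) a
    3'-terminal suffix of the longer chain's junctions, the 3' ends must
    agree within ``z``, and the shorter chain's 5' end must lie within the
    longer chain's corresponding exon (allowing ``a`` of 5' overhang).
    Equal exon counts degenerate to the capped comparison.
    """
    if len(x) == len(y):
        return match_capped(x, y, strand, w)
    if not _spans_overlap(x, y):
        return False
    short, long = (x, y) if len(x) < len(y) else (y, x)
    k, n = len(short), len(long)
    sj_short = [(e[1], f[0]) for e, f in zip(short, short[1:])]
    sj_long = [(e[1], f[0]) for e, f in zip(long, long[1:])]
    if strand == "+":
        # 3'-terminal suffix is the genomic-right end
        suffix = sj_long[n - k:]
        if abs(short[-1][1] - long[-1][1]) > w.z:
            return False
        corresponding = long[n - k]  # exon holding the shorter 5' end
        if short[0][0] < corresponding[0] - w.a:
            return False
        if short[0][0] >= corresponding[1]:
            return False
    else:
        # on -, the 3' end is genomic-left; the suffix is the left prefix
        suffix = sj_long[: k - 1]
        if abs(short[0][0] - long[0][0]) > w.z:
            return False
        corresponding = long[k - 1]
        if short[-1][1] > corresponding[1] + w.a:
            return False
        if short[-1][1] <= corresponding[0]:
            return False
    for (d1, a1), (d2, a2) in zip(sj_short, suffix):
        if abs(d1 - d2) > w.m or abs(a1 - a2) > w.m:
            return False
    return True


def match_chains(
    x: Chain, y: Chain, strand: str, w: WobbleThresholds, mode: str
) -> bool:
    if mode == "capped":
        return match_capped(x, y, strand, w)
    return match_nocap(x, y, strand, w)


# ---------------------------------------------------------------------------
# Grouping (transitive closure of pairwise matches)
# ---------------------------------------------------------------------------

class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[max(ri, rj)] = min(ri, rj)


@dataclass
class ReadGroup:
    """A connected component of the pairwise match relation."""

    chrom: str
    strand: str
    members: list[MappedReadAlignment]
    representative: Chain = ()
    chosen_junctions: list[tuple[int, int]] = field(default_factory=list)
    genomic_polya: bool = False

    @property
    def start(self) -> int:
        return min(m.start for m in self.members)

    @property
    def end(self) -> int:
        return max(m.end for m in self.members)


def group_reads(
    alns: Sequence[MappedReadAlignment], cfg: CollapseConfig
) -> list[ReadGroup]:
    """Group alignments into connected components of the match relation.

    A pair is only eligible when it shares >=1 bp of same-strand overlap
    (the locus condition), which also bounds the sweep: after sorting by
    start, comparisons stop once candidate starts pass the current end.
    """
    groups: list[ReadGroup] = []
    by_key: dict[tuple[str, str], list[MappedReadAlignment]] = {}
    for aln in alns:
        by_key.setdefault((aln.chrom, aln.strand), []).append(aln)
    for (chrom, strand), items in sorted(by_key.items()):
        items = sorted(items, key=lambda a: (a.start, a.end, a.read_id))
        uf = _UnionFind(len(items))
        for i, a in enumerate(items):
            for j in range(i + 1, len(items)):
                b = items[j]
                if b.start >= a.end:
                    break
                if match_chains(a.blocks, b.blocks, strand, cfg.wobble, cfg.mode):
                    uf.union(i, j)
        comp: dict[int, list[MappedReadAlignment]] = {}
        for i, a in enumerate(items):
            comp.setdefault(uf.find(i), []).append(a)
        for root in sorted(comp):
            groups.append(ReadGroup(chrom=chrom, strand=strand, members=comp[root]))
    return groups


def _representative_chain(group: ReadGroup) -> tuple[MappedReadAlignment, Chain]:
    """Longest member defines the representative chain: most junctions,
    then longest span, then earliest 5' start, then read id."""
    def key(m: MappedReadAlignment):
        tss = m.start if group.strand == "+" else -m.end
        return (-(len(m.blocks) - 1), -(m.end - m.start), tss, m.read_id)

    best = min(group.members, key=key)
    return best, best.blocks


def _slot_of(member_junction_idx: int, n_member: int, n_rep: int, strand: str) -> int:
    """Map a member's genomic junction index to the representative's slot,
    anchoring at the 3' end (the end no_cap matching preserves)."""
    if strand == "+":
        return n_rep - n_member + member_junction_idx
    return member_junction_idx


def rank_splice_junctions(
    group: ReadGroup, window: int, ranking: bool = True
) -> list[tuple[int, int]]:
    """Choose one (donor, acceptor) pair per intron slot of the group.

    With ranking on, candidates sort by the cleanest supporting read
    (minimum flanking mismatch count) ascending, then supporting-read count
    descending, then leftmost coordinate.  With ranking off, read coverage
    alone decides (then leftmost).  Chosen coordinates always come from a
    supporting read.
    """
    if not group.members:
        raise ValueError("empty read group")
    _, rep = _representative_chain(group)
    n_rep = len(rep) - 1
    # slot -> candidate (donor, acceptor) -> [flank error counts]
    slots: list[dict[tuple[int, int], list[int]]] = [dict() for _ in range(n_rep)]
    for member in group.members:
        profile = sj_error_profile(member, window)
        n_mem = len(member.blocks) - 1
        for j, junction in enumerate(member.junctions):
            slot = _slot_of(j, n_mem, n_rep, group.strand)
            if 0 <= slot < n_rep:
                errs = profile[j][0] + profile[j][1]
                slots[slot].setdefault(junction, []).append(errs)
    chosen: list[tuple[int, int]] = []
    for slot_candidates in slots:
        if not slot_candidates:
            continue
        if ranking:
            def rank_key(item):
                junction, errs = item
                return (min(errs), -len(errs), junction)
        else:
            def rank_key(item):
                junction, errs = item
                return (-len(errs), junction)
        chosen.append(min(slot_candidates.items(), key=rank_key)[0])
    return chosen


# ---------------------------------------------------------------------------
# Genomic poly-A detection
# ---------------------------------------------------------------------------

def detect_genomic_polya(
    genome: GenomeAccessor,
    chrom: str,
    strand: str,
    tes: int,
    window: int = 20,
    frac: float = 0.7,
) -> bool:
    """True iff the genomic sequence immediately downstream (3') of the
    transcript end is A-rich: >= ``frac`` A content in ``window`` bases on
    the transcript strand.  Windows truncated by the contig end are
    evaluated over the available bases."""
    if strand == "+":
        seq = genome.fetch(chrom, tes, min(tes + window, genome.length(chrom)))
        base = "A"
    else:
        seq = genome.fetch(chrom, max(tes - window, 0), tes)
        base = "T"  # A on the - strand
    if not seq:
        return False
    return seq.count(base) / len(seq) >= frac


# ---------------------------------------------------------------------------
# Full collapse
# ---------------------------------------------------------------------------

@dataclass
class CollapseReports:
    read_decisions: dict[str, tuple[bool, str]]
    trans_read: dict[str, list[str]]
    polya: dict[str, bool]
    alignments: list[MappedReadAlignment]
    n_input: int = 0
    n_pass: int = 0


def _build_model_exons(
    group: ReadGroup, junctions: list[tuple[int, int]]
) -> Chain:
    start = group.start
    end = group.end
    bounds = [start]
    for donor, acceptor in sorted(junctions):
        bounds.extend([donor, acceptor])
    bounds.append(end)
    exons = tuple((bounds[i], bounds[i + 1]) for i in range(0, len(bounds), 2))
    if all(s < e for s, e in exons) and all(
        exons[i][1] <= exons[i + 1][0] for i in range(len(exons) - 1)
    ):
        return exons
    # pathological wobble (e.g. chosen junction outside the extreme span):
    # fall back to the representative chain with extreme ends
    _, rep = _representative_chain(group)
    rep = list(rep)
    rep[0] = (min(start, rep[0][0]), rep[0][1])
    rep[-1] = (rep[-1][0], max(end, rep[-1][1]))
    return tuple(rep)


def collapse(
    alns: Iterable,
    cfg: CollapseConfig,
    genome: GenomeAccessor,
) -> tuple[Annotation, CollapseReports]:
    """Run the full collapse: profile (if needed), filter, group, choose
    splice junctions, and emit the annotation plus evidence reports.

    ``alns`` may be raw pysam records (profiled here against ``genome``) or
    pre-built :class:`MappedReadAlignment` objects.
    """
    from .profile import profile_alignment  # local to avoid cycle at import

    profiled: list[MappedReadAlignment] = []
    for rec in alns:
        if isinstance(rec, MappedReadAlignment):
            profiled.append(rec)
        else:
            profiled.append(profile_alignment(rec, genome))

    decisions: dict[str, tuple[bool, str]] = {}
    passing: list[MappedReadAlignment] = []
    for aln in profiled:
        if not pass_quality(aln, cfg.quality):
            decisions[aln.read_id] = (False, "quality")
            continue
        if cfg.lde_max is not None and not pass_lde(aln, cfg.lde_window, cfg.lde_max):
            decisions[aln.read_id] = (False, "lde")
            continue
        decisions[aln.read_id] = (True, "")
        passing.append(aln)

    groups = group_reads(passing, cfg)
    for g in groups:
        _, g.representative = _representative_chain(g)
        g.chosen_junctions = rank_splice_junctions(
            g, cfg.sj_window, ranking=cfg.sj_ranking
        )

    # loci: connected components of same-strand >=1 bp overlap among groups
    loci: list[list[ReadGroup]] = []
    by_key: dict[tuple[str, str], list[ReadGroup]] = {}
    for g in groups:
        by_key.setdefault((g.chrom, g.strand), []).append(g)
    for key in sorted(by_key):
        items = sorted(by_key[key], key=lambda g: (g.start, g.end))
        current: list[ReadGroup] = []
        cur_end = -1
        for g in items:
            if current and g.start >= cur_end:
                loci.append(current)
                current = []
                cur_end = -1
            current.append(g)
            cur_end = max(cur_end, g.end)
        if current:
            loci.append(current)
    loci.sort(key=lambda L: (L[0].chrom, min(g.start for g in L), L[0].strand))

    models: list[TranscriptModel] = []
    trans_read: dict[str, list[str]] = {}
    polya: dict[str, bool] = {}
    for gi, locus in enumerate(loci, start=1):
        gene_id = f"G{gi}"
        ordered = sorted(
            locus, key=lambda g: (-len(g.members), g.start, g.end)
        )
        for ti, g in enumerate(ordered, start=1):
            tid = f"{gene_id}.{ti}"
            exons = _build_model_exons(g, g.chosen_junctions)
            tes = exons[-1][1] if g.strand == "+" else exons[0][0]
            flagged = detect_genomic_polya(
                genome, g.chrom, g.strand, tes, cfg.polya_window, cfg.polya_fraction
            )
            models.append(
                TranscriptModel(
                    chrom=g.chrom,
                    strand=g.strand,
                    exons=exons,
                    transcript_id=tid,
                    gene_id=gene_id,
                    read_count=len(g.members),
                )
            )
            trans_read[tid] = sorted(m.read_id for m in g.members)
            polya[tid] = flagged

    annotation = Annotation.from_models(models)
    reports = CollapseReports(
        read_decisions=decisions,
        trans_read=trans_read,
        polya=polya,
        alignments=profiled,
        n_input=len(profiled),
        n_pass=len(passing),
    )
    return annotation, reports


def models_as_alignments(annotation: Annotation) -> list[MappedReadAlignment]:
    """View transcript models as error-free pseudo-reads (for re-collapsing
    an annotation or feeding the merge machinery)."""
    out = []
    for m in annotation:
        length = m.spliced_length()
        out.append(
            MappedReadAlignment(
                read_id=m.transcript_id,
                chrom=m.chrom,
                strand=m.strand,
                blocks=m.exons,
                events=(),
                read_length=length,
                mapped_span=length,
                identity=1.0,
                coverage=1.0,
            )
        )
    return out
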