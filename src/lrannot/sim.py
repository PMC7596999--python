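"""Deterministic synthetic fixtures: toy genome, truth annotation, and
pre-mapped spliced reads with controlled noise.

The generator emulates the noise taxonomy of real long-read RNA libraries:

* 5' degradation — a configurable fraction of multi-exon reads is
  truncated at a random exon boundary or partway into an exon, which is
  the signal the degradation-signature statistic detects;
* splice-junction-flanking errors — substitutions/indels planted at an
  elevated per-base rate within a window of each junction (plus a
  background rate elsewhere), the signal the LDE filter removes;
* genomic poly-A tracts — planted immediately downstream of a fraction of
  gene loci, mimicking internal-priming artifacts;
* paralog loci — optional near-identical copies of existing genes.

Reads are emitted pre-mapped (SAM records constructed from truth
coordinates plus planted errors) rather than through an external aligner,
so every byte of output is a deterministic function of the seed.  Transcript
isoforms within a gene are built by skipping internal exons — never by 5'
truncation — so that with zero degradation the capped and no_cap collapses
agree exactly and the expected degradation signature is 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pysam

from .collapse import WobbleThresholds, match_capped, match_nocap
from .models import Annotation, TranscriptModel

BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SimConfig:
    seed: int = 0
    chrom: str = "chr1"
    n_genes: int = 12
    transcripts_per_gene: tuple[int, int] = (1, 3)
    exons_per_transcript: tuple[int, int] = (3, 6)
    exon_length: tuple[int, int] = (80, 250)
    intron_length: tuple[int, int] = (100, 400)
    intergenic_gap: tuple[int, int] = (500, 1500)
    reads_per_transcript: tuple[int, int] = (3, 6)
    degradation_fraction: float = 0.0
    sj_flank_error_rate: float = 0.0  # per-base, within flank_window of a junction
    background_error_rate: float = 0.0  # per-base, elsewhere in exons
    flank_window: int = 20
    junction_shift_max: int = 5  # mis-mapping slip of error-flanked junctions
    polya_plant_fraction: float = 0.0
    polya_tract_length: int = 20
    paralog_pairs: int = 0
    paralog_identity: float = 0.95
    tss_jitter: int = 30
    tes_jitter: int = 30

    def __post_init__(self) -> None:
        for name in ("degradation_fraction", "sj_flank_error_rate",
                     "background_error_rate", "polya_plant_fraction", "paralog_identity"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        for name in ("transcripts_per_gene", "exons_per_transcript", "exon_length",
                     "intron_length", "intergenic_gap", "reads_per_transcript"):
            lo, hi = getattr(self, name)
            if lo > hi or lo < 1:
                raise ValueError(f"contradictory range {name}={lo, hi}")


@dataclass(frozen=True)
class PlantedError:
    ref_pos: int
    kind: str  # substitution | deletion | insertion (all length 1)


@dataclass
class SimRead:
    read_id: str
    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    blocks: tuple[tuple[int, int], ...]
    truncated: bool
    exons_dropped: int
    within_exon_cut: bool
    errors: tuple[PlantedError, ...] = ()
    junction_shifts: tuple[int, ...] = ()  # per junction, 0 = at truth coordinate


@dataclass
class SimResult:
    config: SimConfig
    genome: dict[str, str]
    truth: Annotation
    reads: list[SimRead]
    polya_genes: set[str]

    def read_chains(self) -> list[SimRead]:
        return self.reads


def _rand_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(BASES[rng.integers(0, 4, size=n)])


def _build_gene(
    rng: np.random.Generator, cfg: SimConfig, cursor: int, gene_idx: int,
    skeleton: tuple[tuple[int, int], ...] | None = None,
) -> tuple[list[TranscriptModel], int]:
    """Lay out one gene at ``cursor``; returns its transcripts and new cursor."""
    strand = "+" if rng.random() < 0.5 else "-"
    if skeleton is None:
        n_exons = int(rng.integers(cfg.exons_per_transcript[0], cfg.exons_per_transcript[1] + 1))
        exons = []
        pos = cursor
        for i in range(n_exons):
            length = int(rng.integers(cfg.exon_length[0], cfg.exon_length[1] + 1))
            exons.append((pos, pos + length))
            pos += length
            if i < n_exons - 1:
                pos += int(rng.integers(cfg.intron_length[0], cfg.intron_length[1] + 1))
        skeleton = tuple(exons)
    else:  # paralog: same structure shifted to the new location
        shift = cursor - skeleton[0][0]
        skeleton = tuple((s + shift, e + shift) for s, e in skeleton)
    n_exons = len(skeleton)
    gene_id = f"SIMG{gene_idx}"
    max_tr = 1 + max(0, n_exons - 2)
    n_tr = min(
        int(rng.integers(cfg.transcripts_per_gene[0], cfg.transcripts_per_gene[1] + 1)),
        max_tr,
    )
    models = [
        TranscriptModel(
            chrom=cfg.chrom, strand=strand, exons=skeleton,
            transcript_id=f"{gene_id}.T1", gene_id=gene_id,
        )
    ]
    skippable = list(range(1, n_exons - 1))
    for t in range(2, n_tr + 1):
        skip = skippable[t - 2]
        exons = tuple(e for i, e in enumerate(skeleton) if i != skip)
        models.append(
            TranscriptModel(
                chrom=cfg.chrom, strand=strand, exons=exons,
                transcript_id=f"{gene_id}.T{t}", gene_id=gene_id,
            )
        )
    end = skeleton[-1][1]
    gap = int(rng.integers(cfg.intergenic_gap[0], cfg.intergenic_gap[1] + 1))
    return models, end + gap


def _truncate(
    rng: np.random.Generator, model: TranscriptModel
) -> tuple[tuple[tuple[int, int], ...], int, bool]:
    """5'-truncate a multi-exon chain: drop exons, optionally cut into the
    surviving 5' exon.  Returns (blocks, exons_dropped, within_exon_cut)."""
    exons = list(model.exons)
    n = len(exons)
    n_drop = int(rng.integers(1, n))  # 1 .. n-1
    if model.strand == "+":
        blocks = exons[n_drop:]
    else:
        blocks = exons[: n - n_drop]
    within = False
    if rng.random() < 0.5:
        # cut partway into the (new) 5'-most exon, leaving >= 20 bp
        idx = 0 if model.strand == "+" else -1
        s, e = blocks[idx]
        if e - s > 40:
            cut = int(rng.integers(5, e - s - 20))
            blocks[idx] = (s + cut, e) if model.strand == "+" else (s, e - cut)
            within = True
    return tuple(blocks), n_drop, within


def _jitter_ends(
    rng: np.random.Generator, blocks: list[tuple[int, int]], strand: str,
    cfg: SimConfig, skip_5prime: bool,
) -> list[tuple[int, int]]:
    """Inward jitter of read ends, emulating imprecise transcript ends."""
    def shrink(idx: int, side: str, amount: int) -> None:
        s, e = blocks[idx]
        if side == "left" and e - s - amount >= 10:
            blocks[idx] = (s + amount, e)
        elif side == "right" and e - s - amount >= 10:
            blocks[idx] = (s, e - amount)

    j5 = int(rng.integers(0, cfg.tss_jitter + 1))
    j3 = int(rng.integers(0, cfg.tes_jitter + 1))
    if strand == "+":
        if not skip_5prime:
            shrink(0, "left", j5)
        shrink(len(blocks) - 1, "right", j3)
    else:
        if not skip_5prime:
            shrink(len(blocks) - 1, "right", j5)
        shrink(0, "left", j3)
    return blocks


def _plant_errors_and_shift(
    rng: np.random.Generator, blocks: tuple[tuple[int, int], ...], cfg: SimConfig
) -> tuple[tuple[tuple[int, int], ...], tuple[PlantedError, ...], tuple[int, ...]]:
    """Plant per-base errors and slip error-flanked junctions.

    Per junction, a flank error count is drawn at the elevated rate; a
    junction with at least one flank error is shifted by up to
    ``junction_shift_max`` bases (the mis-mapping that junction-flanking
    errors cause in real alignments).  Error positions are then sampled on
    the shifted blocks, so planted positions always describe the emitted
    alignment exactly.  Background errors cover the remaining exonic bases.
    Indel positions at block edges are demoted to substitutions so the
    CIGAR stays canonical.
    """
    blocks_l = [list(b) for b in blocks]
    w = cfg.flank_window
    n_j = len(blocks_l) - 1
    flank_counts: list[int] = []
    shifts: list[int] = []
    for i in range(n_j):
        left = min(w, blocks_l[i][1] - blocks_l[i][0])
        right = min(w, blocks_l[i + 1][1] - blocks_l[i + 1][0])
        k = int(rng.binomial(left + right, cfg.sj_flank_error_rate)) if cfg.sj_flank_error_rate > 0 else 0
        flank_counts.append(k)
        delta = 0
        if k >= 1 and cfg.junction_shift_max > 0:
            delta = int(rng.integers(1, cfg.junction_shift_max + 1))
            if rng.random() < 0.5:
                delta = -delta
        shifts.append(delta)
    for i, d in enumerate(shifts):
        if d == 0:
            continue
        (s1, e1), (s2, e2) = blocks_l[i], blocks_l[i + 1]
        nd, na = e1 + d, s2 + d
        if nd - s1 >= 10 and e2 - na >= 10 and na - nd >= 20:
            blocks_l[i][1] = nd
            blocks_l[i + 1][0] = na
        else:
            shifts[i] = 0
    shifted = tuple(tuple(b) for b in blocks_l)

    chosen: list[int] = []
    flank: set[int] = set()
    for i in range(n_j):
        donor, acceptor = shifted[i][1], shifted[i + 1][0]
        positions = list(range(max(donor - w, shifted[i][0]), donor)) + list(
            range(acceptor, min(acceptor + w, shifted[i + 1][1]))
        )
        flank.update(positions)
        k = min(flank_counts[i], len(positions))
        if k:
            chosen.extend(rng.choice(positions, size=k, replace=False).tolist())
    body = [p for s, e in shifted for p in range(s, e) if p not in flank]
    if body and cfg.background_error_rate > 0:
        k = rng.binomial(len(body), cfg.background_error_rate)
        if k:
            chosen.extend(rng.choice(body, size=min(k, len(body)), replace=False).tolist())
    edge = {b for s, e in shifted for b in (s, e - 1)}
    errors = []
    for pos in sorted(set(chosen)):
        u = rng.random()
        if u < 0.8 or pos in edge:
            kind = "substitution"
        elif u < 0.9:
            kind = "deletion"
        else:
            kind = "insertion"
        errors.append(PlantedError(int(pos), kind))
    return shifted, tuple(errors), tuple(shifts)


def simulate(cfg: SimConfig, outdir: str | Path | None = None) -> SimResult:
    """Generate the fixture; optionally write genome.fa, truth.bed,
    reads.sam (coordinate-sorted) and the truth tables to ``outdir``.
    A fixed seed yields byte-identical files."""
    rng = np.random.default_rng(cfg.seed)
    models: list[TranscriptModel] = []
    skeletons: list[tuple[tuple[int, int], ...]] = []
    cursor = 1000
    for g in range(1, cfg.n_genes + 1):
        gene_models, cursor = _build_gene(rng, cfg, cursor, g)
        models.extend(gene_models)
        skeletons.append(gene_models[0].exons)
    paralog_of: dict[str, str] = {}
    for p in range(cfg.paralog_pairs):
        if p >= len(skeletons):
            break
        idx = cfg.n_genes + p + 1
        gene_models, cursor = _build_gene(rng, cfg, cursor, idx, skeleton=skeletons[p])
        models.extend(gene_models)
        paralog_of[f"SIMG{idx}"] = f"SIMG{p + 1}"
    truth = Annotation.from_models(models)

    genome_len = cursor + 1000
    seq = np.array(list(_rand_seq(rng, genome_len)))

    # paralog loci copy their source sequence with (1 - identity) substitutions
    for para_gid, src_gid in paralog_of.items():
        src = truth.get(f"{src_gid}.T1")
        dst = truth.get(f"{para_gid}.T1")
        s0, d0 = src.start, dst.start
        span = src.end - src.start
        copied = seq[s0 : s0 + span].copy()
        n_mut = rng.binomial(span, 1.0 - cfg.paralog_identity)
        if n_mut:
            for pos in rng.choice(span, size=n_mut, replace=False):
                alt = [b for b in "ACGT" if b != copied[pos]]
                copied[pos] = alt[int(rng.integers(0, 3))]
        seq[d0 : d0 + span] = copied

    # plant genomic poly-A tracts downstream of a fraction of genes
    gene_ids = sorted(truth.loci, key=lambda g: int(g.removeprefix("SIMG")))
    n_polya = int(round(cfg.polya_plant_fraction * len(gene_ids)))
    polya_genes: set[str] = set()
    if n_polya:
        picked = rng.choice(len(gene_ids), size=n_polya, replace=False)
        for i in sorted(picked.tolist()):
            gid = gene_ids[i]
            first = truth.get(truth.loci[gid][0])
            if first.strand == "+":
                seq[first.end : first.end + cfg.polya_tract_length] = "A"
            else:
                seq[max(first.start - cfg.polya_tract_length, 0) : first.start] = "T"
            polya_genes.add(gid)

    genome = {cfg.chrom: "".join(seq)}

    # reads
    reads: list[SimRead] = []
    counter = 0
    for model in truth:
        n_reads = int(rng.integers(cfg.reads_per_transcript[0], cfg.reads_per_transcript[1] + 1))
        for _ in range(n_reads):
            counter += 1
            truncated = False
            dropped = 0
            within = False
            blocks = list(model.exons)
            if model.n_exons > 1 and rng.random() < cfg.degradation_fraction:
                truncated = True
                blocks_t, dropped, within = _truncate(rng, model)
                blocks = list(blocks_t)
            blocks = _jitter_ends(rng, blocks, model.strand, cfg, skip_5prime=truncated)
            chain, errors, shifts = _plant_errors_and_shift(rng, tuple(blocks), cfg)
            reads.append(
                SimRead(
                    read_id=f"r{counter:06d}",
                    transcript_id=model.transcript_id,
                    gene_id=model.gene_id,
                    chrom=cfg.chrom,
                    strand=model.strand,
                    blocks=chain,
                    truncated=truncated,
                    exons_dropped=dropped,
                    within_exon_cut=within,
                    errors=errors,
                    junction_shifts=shifts,
                )
            )

    result = SimResult(config=cfg, genome=genome, truth=truth, reads=reads, polya_genes=polya_genes)
    if outdir is not None:
        write_fixture(result, Path(outdir))
    return result


# ---------------------------------------------------------------------------
# SAM construction
# ---------------------------------------------------------------------------

def _read_to_sam(read: SimRead, genome: str, header: pysam.AlignmentHeader) -> pysam.AlignedSegment:
    ops: list[tuple[int, int]] = []  # (op, len) — 0=M 1=I 2=D 3=N
    seq_parts: list[str] = []

    def push(op: int, length: int) -> None:
        if length <= 0:
            return
        if ops and ops[-1][0] == op:
            ops[-1] = (op, ops[-1][1] + length)
        else:
            ops.append((op, length))

    errs_by_block: dict[int, list[PlantedError]] = {}
    for e in read.errors:
        for bi, (s, en) in enumerate(read.blocks):
            if s <= e.ref_pos < en:
                errs_by_block.setdefault(bi, []).append(e)
                break

    rng_local = np.random.default_rng(abs(hash(read.read_id)) % (2**31))
    for bi, (s, en) in enumerate(read.blocks):
        if bi > 0:
            push(3, s - read.blocks[bi - 1][1])
        cur = s
        for e in sorted(errs_by_block.get(bi, []), key=lambda x: x.ref_pos):
            if e.kind == "substitution":
                continue  # handled in sequence
            push(0, e.ref_pos - cur)
            seq_parts.append(genome[cur : e.ref_pos])
            if e.kind == "deletion":
                push(2, 1)
                cur = e.ref_pos + 1
            else:  # insertion anchored at the left flank of ref_pos
                push(1, 1)
                seq_parts.append("ACGT"[int(rng_local.integers(0, 4))])
                cur = e.ref_pos
        push(0, en - cur)
        seq_parts.append(genome[cur:en])

    seq = list("".join(seq_parts))
    # apply substitutions: positions must be located within the built sequence
    offset_map: dict[int, int] = {}
    qpos = 0
    ref = read.blocks[0][0]
    for op, length in ops:
        if op == 0:
            for k in range(length):
                offset_map[ref + k] = qpos + k
            ref += length
            qpos += length
        elif op == 1:
            qpos += length
        elif op in (2, 3):
            ref += length
    for e in read.errors:
        if e.kind == "substitution" and e.ref_pos in offset_map:
            q = offset_map[e.ref_pos]
            alt = [b for b in "ACGT" if b != seq[q].upper()]
            seq[q] = alt[int(rng_local.integers(0, 3))]

    rec = pysam.AlignedSegment(header)
    rec.query_name = read.read_id
    rec.reference_name = read.chrom
    rec.reference_start = read.blocks[0][0]
    rec.mapping_quality = 60
    rec.flag = 16 if read.strand == "-" else 0
    rec.cigartuples = ops
    rec.query_sequence = "".join(seq)
    return rec


def write_fixture(result: SimResult, outdir: Path) -> dict[str, Path]:
    """Write genome.fa, truth.bed, reads.sam and the truth tables."""
    from . import io

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "genome": outdir / "genome.fa",
        "truth": outdir / "truth.bed",
        "reads": outdir / "reads.sam",
        "reads_table": outdir / "reads.tsv",
        "errors_table": outdir / "errors.tsv",
        "polya_table": outdir / "polya.tsv",
    }
    with open(paths["genome"], "w") as fh:
        for chrom in sorted(result.genome):
            fh.write(f">{chrom}\n")
            s = result.genome[chrom]
            for i in range(0, len(s), 60):
                fh.write(s[i : i + 60] + "\n")
    io.write_bed12(result.truth, paths["truth"])

    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "coordinate"},
            "SQ": [
                {"SN": chrom, "LN": len(result.genome[chrom])}
                for chrom in sorted(result.genome)
            ],
        }
    )
    records = [
        _read_to_sam(r, result.genome[r.chrom], header) for r in result.reads
    ]
    records.sort(key=lambda r: (r.reference_name, r.reference_start, r.query_name))
    with pysam.AlignmentFile(str(paths["reads"]), "w", header=header) as out:
        for rec in records:
            out.write(rec)

    with open(paths["reads_table"], "w") as fh:
        fh.write("read_id\ttranscript_id\tgene_id\tstrand\ttruncated\texons_dropped\twithin_exon_cut\tn_blocks\tstart\tend\tjunction_shifts\n")
        for r in result.reads:
            fh.write(
                f"{r.read_id}\t{r.transcript_id}\t{r.gene_id}\t{r.strand}\t"
                f"{int(r.truncated)}\t{r.exons_dropped}\t{int(r.within_exon_cut)}\t"
                f"{len(r.blocks)}\t{r.blocks[0][0]}\t{r.blocks[-1][1]}\t"
                f"{','.join(map(str, r.junction_shifts)) or '.'}\n"
            )
    with open(paths["errors_table"], "w") as fh:
        fh.write("read_id\tref_pos\tkind\n")
        for r in result.reads:
            for e in r.errors:
                fh.write(f"{r.read_id}\t{e.ref_pos}\t{e.kind}\n")
    with open(paths["polya_table"], "w") as fh:
        fh.write("gene_id\tplanted\n")
        for gid in sorted(result.truth.loci):
            fh.write(f"{gid}\t{int(gid in result.polya_genes)}\n")
    return paths


# ---------------------------------------------------------------------------
# Truth-side expectation for the degradation signature
# ---------------------------------------------------------------------------

def degsig_truth(
    result: SimResult, wobble: WobbleThresholds = WobbleThresholds()
) -> tuple[int, int]:
    """Exact (CT, NT) a correct collapser must produce on these reads,
    by brute-force transitive closure of the pairwise matchers (full O(n^2),
    independent of the production sweep)."""

    def count(mode: str) -> int:
        reads = result.reads
        n = len(reads)
        match_fn = match_capped if mode == "capped" else match_nocap
        adj = [[False] * n for _ in range(n)]
        for i in range(n):
            for j in range(i + 1, n):
                a, b = reads[i], reads[j]
                if a.strand != b.strand or a.chrom != b.chrom:
                    continue
                if a.blocks[0][0] >= b.blocks[-1][1] or b.blocks[0][0] >= a.blocks[-1][1]:
                    continue
                if match_fn(a.blocks, b.blocks, a.strand, wobble):
                    adj[i][j] = adj[j][i] = True
        seen = [False] * n
        groups: list[list[int]] = []
        for i in range(n):
            if seen[i]:
                continue
            stack, comp = [i], []
            seen[i] = True
            while stack:
                u = stack.pop()
                comp.append(u)
                for v in range(n):
                    if adj[u][v] and not seen[v]:
                        seen[v] = True
                        stack.append(v)
            groups.append(comp)
        # loci: overlap components among groups (same strand)
        spans = [
            (
                reads[g[0]].chrom,
                reads[g[0]].strand,
                min(reads[i].blocks[0][0] for i in g),
                max(reads[i].blocks[-1][1] for i in g),
                g,
            )
            for g in groups
        ]
        m = len(spans)
        gadj = [[False] * m for _ in range(m)]
        for i in range(m):
            for j in range(i + 1, m):
                c1, s1, a1, b1, _ = spans[i]
                c2, s2, a2, b2, _ = spans[j]
                if c1 == c2 and s1 == s2 and a1 < b2 and a2 < b1:
                    gadj[i][j] = gadj[j][i] = True
        gseen = [False] * m
        total = 0
        for i in range(m):
            if gseen[i]:
                continue
            stack, comp = [i], []
            gseen[i] = True
            while stack:
                u = stack.pop()
                comp.append(u)
                for v in range(m):
                    if gadj[u][v] and not gseen[v]:
                        gseen[v] = True
                        stack.append(v)
            locus_reads = sum(len(spans[k][4]) for k in comp)
            if locus_reads > 1:
                total += sum(
                    1
                    for k in comp
                    if max(len(reads[i].blocks) for i in spans[k][4]) > 1
                )
        return total

    return count("capped"), count("no_cap")
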