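"""ORF prediction, NMD labeling and peptide export for homology search.

Per transcript, the longest stop-terminated ORF is taken in each of the
three forward frames (the spliced sequence is already strand-corrected, so
reverse frames are never consulted).  A start codon is not required; an ORF
without one is itself evidence that the transcript may come from degraded
(5'-incomplete) RNA.  A transcript is an NMD (nonsense-mediated decay)
candidate when its stop codon lies at least 50 nt upstream of the final
exon-exon junction — the canonical 50-nt rule.

Homology search is an interface, not an internal call: peptides are written
as FASTA and standard tabular results (outfmt-6-style columns) are read
back to pick the best-supported frame per transcript.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from Bio.Seq import Seq

from .models import Annotation, TranscriptModel
from .profile import GenomeAccessor

STOPS = {"TAA", "TAG", "TGA"}


@dataclass(frozen=True)
class OrfAnnotation:
    transcript_id: str
    frame: int  # 0, 1 or 2
    orf_start: int  # transcript coordinate, 0-based
    orf_stop: int  # exclusive; includes the stop codon
    has_start: bool
    peptide: str

    def __post_init__(self) -> None:
        if (self.orf_stop - self.orf_start) % 3 != 0:
            raise ValueError("ORF length must be a multiple of 3")

    @property
    def n_codons(self) -> int:
        return (self.orf_stop - self.orf_start) // 3


def find_orfs(seq: str, transcript_id: str = "") -> list[OrfAnnotation]:
    """Longest stop-terminated ORF in each forward frame.

    An ORF candidate runs from the base after the previous stop codon (or
    the frame start) through a stop codon inclusive.  Frames with no stop
    codon yield nothing; sequences shorter than 3 nt yield an empty list.
    Ties go to the 5'-most candidate.
    """
    seq = seq.upper()
    out: list[OrfAnnotation] = []
    for frame in range(3):
        best: tuple[int, int] | None = None
        region_start = frame
        pos = frame
        while pos + 3 <= len(seq):
            codon = seq[pos : pos + 3]
            if codon in STOPS:
                cand = (region_start, pos + 3)
                if best is None or (cand[1] - cand[0]) > (best[1] - best[0]):
                    best = cand
                region_start = pos + 3
            pos += 3
        if best is None:
            continue
        start, stop = best
        coding = seq[start : stop - 3]
        peptide = str(Seq(coding).translate()) if coding else ""
        out.append(
            OrfAnnotation(
                transcript_id=transcript_id,
                frame=frame,
                orf_start=start,
                orf_stop=stop,
                has_start=seq[start : start + 3] == "ATG",
                peptide=peptide,
            )
        )
    return out


def last_junction_position(model: TranscriptModel) -> int | None:
    """Transcript coordinate of the final exon-exon junction (None for
    single-exon models): the spliced length minus the 3'-terminal exon."""
    if model.n_exons == 1:
        return None
    last_exon = model.exons[-1] if model.strand == "+" else model.exons[0]
    return model.spliced_length() - (last_exon[1] - last_exon[0])


def label_nmd(model: TranscriptModel, orf: OrfAnnotation, min_distance: int = 50) -> bool:
    """NMD candidate: stop codon >= ``min_distance`` nt upstream (in
    transcript coordinates) of the final splice junction.  Inclusive at
    exactly ``min_distance``; single-exon transcripts are never NMD."""
    junction = last_junction_position(model)
    if junction is None:
        return False
    return junction - orf.orf_stop >= min_distance


# ---------------------------------------------------------------------------
# Homology-search interface
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HomologyHit:
    transcript_id: str
    frame: int
    subject: str
    pident: float
    length: int
    evalue: float
    bitscore: float


def read_homology_table(path) -> list[HomologyHit]:
    """Parse outfmt-6-style tabular results whose qseqid is
    ``transcript_id|frameN`` (as written by :func:`write_peptides`)."""
    hits: list[HomologyHit] = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            qseqid, sseqid, pident, length = fields[0], fields[1], fields[2], fields[3]
            evalue, bitscore = fields[-2], fields[-1]
            tid, frame_tag = qseqid.rsplit("|", 1)
            hits.append(
                HomologyHit(
                    transcript_id=tid,
                    frame=int(frame_tag.removeprefix("frame")),
                    subject=sseqid,
                    pident=float(pident),
                    length=int(length),
                    evalue=float(evalue),
                    bitscore=float(bitscore),
                )
            )
    return hits


def select_best_orf(
    orfs: Sequence[OrfAnnotation], hits: Iterable[HomologyHit] = ()
) -> tuple[OrfAnnotation | None, bool]:
    """Pick the predicted true ORF for one transcript.

    With hits, the frame of the best hit wins (bitscore descending, then
    E-value ascending) and the transcript is coding.  Without hits the
    longest ORF wins and the transcript is a non-coding candidate.
    Returns ``(orf, coding)``; orf is None when no frame had an ORF.
    """
    orfs = list(orfs)
    if not orfs:
        return None, False
    by_frame = {o.frame: o for o in orfs}
    scored = [h for h in hits if h.frame in by_frame]
    if scored:
        best = min(scored, key=lambda h: (-h.bitscore, h.evalue))
        return by_frame[best.frame], True
    longest = max(orfs, key=lambda o: (o.orf_stop - o.orf_start, -o.frame))
    return longest, False


# ---------------------------------------------------------------------------
# Sequence extraction and peptide export
# ---------------------------------------------------------------------------

def transcript_sequence(model: TranscriptModel, genome: GenomeAccessor) -> str:
    """Spliced, strand-corrected (5'->3') transcript sequence."""
    seq = "".join(genome.fetch(model.chrom, s, e) for s, e in model.exons)
    if model.strand == "-":
        seq = str(Seq(seq).reverse_complement())
    return seq


def write_peptides(
    annotation: Annotation, genome: GenomeAccessor, path
) -> dict[str, list[OrfAnnotation]]:
    """Write per-frame peptides as FASTA (ids ``transcript_id|frameN``) and
    return the predicted ORFs keyed by transcript."""
    orfs_by_tid: dict[str, list[OrfAnnotation]] = {}
    with open(path, "w") as fh:
        for model in annotation.sorted():
            seq = transcript_sequence(model, genome)
            orfs = find_orfs(seq, model.transcript_id)
            orfs_by_tid[model.transcript_id] = orfs
            for o in orfs:
                if o.peptide:
                    fh.write(f">{model.transcript_id}|frame{o.frame}\n{o.peptide}\n")
    return orfs_by_tid


@dataclass(frozen=True)
class OrfLabel:
    orf: OrfAnnotation | None
    coding: bool
    nmd: bool
    degraded_evidence: bool  # ORF without a start codon


def annotate_orfs(
    annotation: Annotation,
    genome: GenomeAccessor,
    hits: Iterable[HomologyHit] = (),
) -> dict[str, OrfLabel]:
    """Full per-transcript ORF/NMD labeling."""
    hits_by_tid: dict[str, list[HomologyHit]] = {}
    for h in hits:
        hits_by_tid.setdefault(h.transcript_id, []).append(h)
    out: dict[str, OrfLabel] = {}
    for model in annotation:
        seq = transcript_sequence(model, genome)
        orfs = find_orfs(seq, model.transcript_id)
        best, coding = select_best_orf(orfs, hits_by_tid.get(model.transcript_id, ()))
        nmd = label_nmd(model, best) if best is not None else False
        degraded = best is not None and not best.has_start
        out[model.transcript_id] = OrfLabel(best, coding, nmd, degraded)
    return out


def write_orf_report(labels: Mapping[str, OrfLabel], path) -> None:
    cols = ["transcript_id", "frame", "orf_start", "orf_stop", "has_start", "coding", "nmd", "degraded_evidence"]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for tid in sorted(labels):
            lab = labels[tid]
            if lab.orf is None:
                fh.write(f"{tid}\t.\t.\t.\t.\t{lab.coding}\t{lab.nmd}\t{lab.degraded_evidence}\n")
            else:
                o = lab.orf
                fh.write(
                    f"{tid}\t{o.frame}\t{o.orf_start}\t{o.orf_stop}\t{o.has_start}\t"
                    f"{lab.coding}\t{lab.nmd}\t{lab.degraded_evidence}\n"
                )
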