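"""Merge a long-read annotation with a reference, giving the reference
priority for coordinates.

A 5'-truncated long-read model (no_cap source) absorbs into the matching
reference model (capped source, priority 1,1,1) and adopts its splice
junctions and transcript ends.
"""

from lrannot import Annotation, MergeSourceSpec, TranscriptModel, WobbleThresholds, merge

reference = Annotation.from_models([
    TranscriptModel("chr1", "+", ((100, 200), (400, 500), (700, 800)), "ENST1", "ENSG1"),
])
long_read = Annotation.from_models([
    # truncated: starts inside exon 2, junctions wobble by a few bp
    TranscriptModel("chr1", "+", ((420, 498), (703, 790)), "LR1", "LRG1"),
    # novel locus absent from the reference
    TranscriptModel("chr1", "+", ((5000, 5400),), "LR2", "LRG2"),
])

merged, report = merge(
    [
        MergeSourceSpec(None, "longread", mode="no_cap", priority=(2, 2, 2), annotation=long_read),
        MergeSourceSpec(None, "reference", mode="capped", priority=(1, 1, 1), annotation=reference),
    ],
    WobbleThresholds(a=100, m=10, z=100),
)

for m in merged:
    contribs = ", ".join(f"{lbl}:{tid}" for lbl, tid in report.transcripts[m.transcript_id])
    print(f"{m.transcript_id}  exons={m.exons}  from [{contribs}]")
# The first merged model carries the reference coordinates (priority 1)
# even though a long-read model contributed; the novel locus survives as
# its own gene with only the long-read source behind it.
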