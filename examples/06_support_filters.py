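"""Trace read support and filter an annotation.

Shows the three post-collapse filters: fragment removal, minimum-support
filtering (the two-flowcell rule), and reference-guided filtering.
"""

from lrannot import (
    Annotation,
    ReadSupport,
    TranscriptModel,
    WobbleThresholds,
    filter_by_support,
    guided_filter,
    remove_fragments,
)

CHAIN = ((100, 200), (400, 500), (700, 800))
ann = Annotation.from_models([
    TranscriptModel("chr1", "+", CHAIN, "G1.1", "G1"),
    TranscriptModel("chr1", "+", ((150, 200), (400, 480)), "G1.frag", "G1"),
    TranscriptModel("chr1", "+", ((5000, 5400),), "G2.1", "G2"),
])

kept = remove_fragments(ann, m=0)
print(f"fragment filter: kept {[m.transcript_id for m in kept]}")
# G1.frag shares G1.1's internal structure but is shorter on both ends.

support = ReadSupport(transcripts={
    "G1.1": {("cell1", "r1"), ("cell2", "r2")},
    "G2.1": {("cell1", "r3")},
})
kept = filter_by_support(kept, support, min_count=2, unit="sources")
print(f"two-source rule: kept {[m.transcript_id for m in kept]}")
# Only models seen by both sequencing cells survive.

reference = Annotation.from_models([TranscriptModel("chr1", "+", CHAIN, "R.1", "R")])
guided, _ = guided_filter(ann, reference, WobbleThresholds(100, 10, 100))
print(f"guided filter: {len(guided)} model(s) with reference coordinates "
      f"{[m.exons for m in guided]}")
# Only long-read models matching the reference are kept, and they adopt
# the reference's splice junctions and ends.
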