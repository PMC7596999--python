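"""Collapse simulated long reads into transcript models.

Generates a small synthetic dataset (toy genome + pre-mapped spliced
reads), runs the full collapse with LDE filtering, and prints the
resulting models.
"""

from lrannot import (
    CollapseConfig,
    GenomeAccessor,
    WobbleThresholds,
    collapse,
    profile_alignment,
    read_alignments,
    simulate,
)
from lrannot.sim import SimConfig
import tempfile
from pathlib import Path

with tempfile.TemporaryDirectory() as tmp:
    sim = simulate(
        SimConfig(seed=1, n_genes=4, sj_flank_error_rate=0.02, degradation_fraction=0.2),
        Path(tmp),
    )
    genome = GenomeAccessor(sim.genome)
    cfg = CollapseConfig(
        mode="no_cap",
        wobble=WobbleThresholds(a=100, m=10, z=100),
        lde_window=20,
        lde_max=1,
    )
    alns = [profile_alignment(r, genome) for r in read_alignments(Path(tmp) / "reads.sam")]
    annotation, reports = collapse(alns, cfg, genome)

print(f"{reports.n_pass}/{reports.n_input} reads passed quality + LDE filtering")
print(f"{len(annotation)} transcript models in {len(annotation.loci)} genes "
      f"(truth had {len(sim.truth)} transcripts in {len(sim.truth.loci)} genes):")
for m in annotation:
    print(f"  {m.transcript_id}  {m.chrom}:{m.start}-{m.end} ({m.strand})  "
          f"{m.n_exons} exons, {m.read_count} reads")
# Each model is one group of reads whose exon-intron structures matched
# within the wobble thresholds; read_count is the group's size.
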