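# Methods

## The problem

Long-read RNA sequencing (PacBio Iso-Seq, Nanopore cDNA) reads whole
transcripts, but the raw material is noisy in ways that corrupt
genome-based transcriptome annotation: sequencing errors near splice
junctions shift the mapped exon boundaries (*wobble*), partially degraded
RNA yields 5'-incomplete reads that masquerade as alternative transcription
start sites, and internal priming on genomic A-tracts produces false 3'
ends.  `lrannot` builds transcript models from spliced alignments while
controlling each of these error modes explicitly, and provides statistics
to quantify how much of each mode a library contains.

## Transcript models and coordinates

A transcript model is a strand-aware chain of exons on one chromosome.
Coordinates are 0-based half-open everywhere (the BED convention); GTF
input is converted at its parsing boundary only.  A splice junction is the
`(donor end, acceptor start)` pair of adjacent exons.  BED12 with the name
field `gene_id;transcript_id` is the native annotation dialect; a bare name
is tolerated and duplicated into both ids.  Strand `.` is rejected because
every grouping operation is strand-aware.

## Read profiling and filters

Each primary spliced alignment is converted into a mismatch-event profile:
soft clips, insertions, deletions, and per-base substitutions (hard clips
excluded throughout).  Substitutions are called by comparing the read
sequence to the genome over aligned blocks; substitution runs are
decomposed into length-1 events so windowed counts are base-accurate.
Deletions occupy their reference interval; insertions and clips carry all
their bases at a single anchor coordinate (left flank / alignment edge).

Two per-read filters precede collapsing:

* **Quality** — alignment coverage (non-clipped fraction of the read) and
  identity (1 − mismatch bases / read length, clips included) must each
  meet a threshold.  Including clips in identity follows the same
  accounting as the overall mismatch-rate summary; the alternative
  (clip-free identity) is noted as a possible variant but not implemented.
* **Local density error (LDE)** — for every junction, the mismatch bases
  within a window (default 20 bp) on the exonic sides must not exceed a
  cap.  Only exonic-side bases count, window inclusive at exactly the
  window distance; intron interiors are unaligned so no events can fall
  there.  Reads violating the cap at any junction are discarded whole;
  single-exon reads pass vacuously.

## Wobble matching and collapsing

Reads are grouped by pairwise chain matching with inclusive wobble
thresholds: `a` bases at the 5' start, `m` at every junction boundary, `z`
at the 3' end ("within" is read as ≤).  A pair is only compared when it
shares ≥1 bp of same-strand overlap — the locus condition — which also
lets the sweep implementation prune comparisons exactly.

* **capped** mode requires equal exon counts and all boundaries matched —
  appropriate when the library selects 5'-capped, full-length molecules.
* **no_cap** mode additionally lets a shorter chain merge into a longer
  one when its whole junction chain matches a 3'-terminal suffix of the
  longer chain's, the 3' ends agree within `z`, and its 5' end lies inside
  the longer model's corresponding exon (with up to `a` of overhang).  A
  single-exon read merges when it sits inside the longer model's
  3'-terminal exon with the 3' ends within `z`.

Groups are connected components of this relation (union-find over the
sweep).  Transitivity means *wobble walking* is accepted by design:
staggered boundaries each within the threshold can chain into a total
spread exceeding it.  Exact duplicate chains always merge because all
thresholds are inclusive at distance 0.

Each group becomes one model.  The representative chain is the longest
member (most junctions, then longest span, then earliest 5' start, then
read id).  Members' junctions are assigned to representative slots
anchored at the 3' end — the end the no_cap match preserves.  Per slot,
candidate coordinates are ranked by the cleanest supporting read (minimum
flanking mismatch bases) ascending, then supporting-read count descending,
then leftmost; with ranking off, read count then leftmost.  The chosen
coordinate therefore always comes from an observed read.  The model span
takes the extreme 5'-most and 3'-most member ends; if a chosen junction
falls outside a constructible chain (a wobble pathology), the
representative chain with extreme ends is used instead.  Gene loci are
connected components of same-strand ≥1 bp overlap among groups; ids are
`G{n}` in coordinate order with transcripts numbered by descending read
count.

Genomic poly-A detection reports models whose downstream genomic window
(default 20 bp, strand-aware) is ≥70 % A.  The defaults are chosen so that
a random 25 %-A sequence essentially never triggers the flag
(P(≥14 A in 20) ≈ 4·10⁻⁵) while true primed A-tracts of ≥14 bp always do.

## Merging annotations

Merging applies the same matchers to transcript models from multiple
sources, each carrying a collapse mode and a `(TSS, SJ, TES)` priority
triple (1 = highest).  A mixed pair — one capped source, one no_cap —
is compared under no_cap; this is the rule that lets truncated long-read
models absorb into full-length reference models.  Within a merged group,
junctions come from the highest-SJ-priority source present (ties: most
contributors, then leftmost), and each end comes from the extreme end
among the members of the highest-priority source for that end.  Junction
slots 5' of the chosen span (possible when a low-priority member extends
past the priority source's start) are dropped.  Reports record, per final
model, its contributors and signed per-boundary offsets (final −
contributor), which feed the wobble analysis directly.  With equal
priorities the result is independent of source order: every tie-break uses
counts and coordinates, never input order.

## Read support and filters

Collapse emits a model → read-id trace; merge emits a final-model →
contributor trace.  Support resolution composes these transitively, so a
model that went through any number of merges still maps to its original
read ids; a dangling contributor is an error, not a silent drop.  On top
of support:

* **Fragment removal** drops a model whose full junction chain occurs as a
  *contiguous* subchain (within `m`) of another model that extends
  strictly beyond it on both genomic ends.  Strictness prevents exact
  duplicates from removing each other; contiguity enforces identical
  internal structure rather than a mere subsequence.  A single-exon model
  is a fragment when it lies strictly inside any single exon of another
  model — this covers both a longer mono-exonic container and an internal
  exon of a spliced model, which are the same evidence situation.
* **Support filtering** keeps transcripts (or whole genes) with at least
  `s` distinct reads, or distinct source labels — the latter implements
  the "supported by both flowcells" rule.
* **Guided filtering** merges the long-read annotation (no_cap, priority
  2,2,2) with a reference (capped, priority 1,1,1) and keeps models with
  contributors from both sources; surviving models carry reference
  coordinates by construction.

## Degradation signature

Collapsing the same reads under both modes measures 5' degradation:
`DegSig = (CT − NT)/CT`, where CT and NT count multi-exon transcript
models from genes with more than one supporting read in the capped and
no_cap runs.  "More than one read support" is evaluated at the gene level
(total distinct reads over the gene's transcripts), which is what the
formula's wording supports; a per-transcript reading would inflate CT with
singleton models.  Truncation-derived models exist only in the capped run,
so DegSig is the fraction of models explained by 5' truncation: 0 when the
runs agree, approaching 1 when most capped models merge away.  NT ≤ CT
always, because no_cap can only merge groups relative to capped, never
split them.  Alternative TSSs and incomplete first-strand synthesis also
create 5' variability, so the statistic is a proxy, not a measurement; on
data where truncations bridge several isoforms of a gene it responds
super-linearly to the truncated-read fraction.

## Wobble against a reference, and read jumbling

`sj_wobble` matches query to reference transcripts (same junction count,
each boundary within 30 bp by default, ends within 300 bp) and reports
signed per-junction offsets, excluding transcript ends, whose natural
variance would swamp the junction signal.  `find_model_changes` inverts a
merged annotation's read support: any read supporting more than one final
model is a jumble event, gene-level when the models belong to different
genes — the signature of inter-read error correction reassigning reads.

## ORF and NMD labeling

Per transcript (spliced, strand-corrected sequence), the longest
stop-terminated ORF is taken in each forward frame; reverse frames are
never consulted.  An ORF runs from the frame start or the base after the
previous stop codon through the stop codon inclusive; a start codon is not
required, and its absence is recorded as degraded-RNA evidence.  A
transcript is an NMD candidate when its stop codon ends ≥50 nt (inclusive)
upstream of the *final* exon-exon junction — the canonical rule; applying
it to any junction would be strictly more permissive and is not what the
50-nt mechanism describes.  Homology search is an interface: peptides go
out as FASTA (`id|frameN`), tabular results come back, and the
best-scoring frame (bitscore desc, E-value asc) wins; transcripts with no
hits keep their longest ORF and are labeled non-coding candidates.

## Synthetic data

The simulator generates a toy chromosome of random sequence with 12 genes
by default (3–6 exons of 80–250 bp, introns 100–400 bp, 1–3 isoforms per
gene, 3–6 reads per transcript), emitting reads as pre-mapped SAM records
so no aligner nondeterminism enters the tests.  Within-gene isoforms are
built by skipping *internal* exons — never by 5' truncation — so that at
zero degradation the capped and no_cap collapses agree exactly and the
expected DegSig is 0.  Controlled noise:

* 5' degradation: a configurable fraction of multi-exon reads is
  truncated at a random exon boundary (half the time also partway into
  the surviving 5' exon);
* read ends jitter inward by up to 30 bp, within the default `a`/`z`
  wobble so end imprecision never changes grouping;
* errors are planted per base at an elevated rate within 20 bp of
  junctions and a background rate elsewhere (80 % substitutions, 10 %
  deletions, 10 % insertions, length 1; indels at block edges are demoted
  to substitutions to keep CIGARs canonical);
* a junction that received flank errors is slipped by up to 5 bp —
  within the default junction wobble — emulating the mis-mapping that
  flank errors cause; the emitted sequence is taken from the slipped
  coordinates, so the planted-error table describes the alignment
  exactly;
* genomic A-tracts (20 bp) are planted downstream of a chosen fraction of
  genes, and optional paralog loci copy a gene's structure at ~95 %
  sequence identity.

What the simulator does **not** model: realistic platform error spectra
and quality scores, chimeric/fusion reads, expression-level imbalance,
intron retention, and mapping ambiguity (each read is emitted at its true
locus).  Tests passing on this material therefore demonstrate algorithmic
correctness — grouping, filtering, ranking, and the statistics computing
what they are defined to compute — not end-to-end accuracy on real
libraries.

The truth-side oracle `degsig_truth` recomputes the exact CT/NT a correct
collapser must produce by full O(n²) transitive closure over the truth
read chains, independent of the production sweep; the acceptance checks
compare the pipeline against it.

## Numerical and design choices

* All wobble thresholds inclusive; defaults `a=100, m=10, z=100` (the
  mid-range of the settings used in practice for this class of data).
* Ties everywhere break on counts, then coordinates (leftmost), then
  lexicographic ids — never on input order, making outputs byte-stable.
* Degenerate inputs: empty read sets collapse to empty annotations;
  windows truncated by contig ends evaluate over available bases; CT = 0
  reports DegSig as unavailable rather than 0.
* Problem sizes in the test suite and acceptance script (12–20 genes,
  ~100–300 reads, 200 random grouping instances, 300 random ORF
  sequences) are chosen so each check exercises every code path while the
  whole suite stays interactive-fast.

## Known limitations

* The SJ rank is the stated ordering principle (cleanest supporting read
  first), not a discrete tier scheme; with very deep coverage a
  frequency-weighted rank might be preferable.
* Identity includes soft-clipped bases; heavily clipped but otherwise
  perfect alignments score low on both coverage and identity.
* `three_prime_match_compare` classifies equal-exon-count pairs by exact
  TSS comparison; sub-wobble 5' differences are reported as longer/shorter
  rather than equal.
* Gene-locus assignment is span-overlap based; interleaved genes sharing
  a strand within one span are fused into one locus id.
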