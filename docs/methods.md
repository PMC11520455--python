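# Methods

## Pipeline model

The pipeline operates purely on coordinates.  Its atom is the 21-column
PSL record; a liftover step upstream (outside this package) projects a
reference region through a multi-genome alignment and emits one PSL file
per reference/species pair, plus pairwise files between species that are
adjacent in the display order.  All internal coordinates are 0-based
half-open; conversion to/from GFF3's 1-based closed convention and PSL's
reverse-strand query coordinates happens only at the format boundary.

**Assembly.**  Records are grouped by (target sequence, strand), sorted
by target start, and chained while the next record starts within
`gap_value` bp of the running end of the chain.  The gap is measured on
target coordinates only; query colinearity is recorded (the fragment's
query span) but not enforced, because liftover output is target-ordered
per chain and a query-side condition would split fragments at query-side
indels.  This threshold chaining equals the transitive merge closure of
pairwise-chainable records (tested against a brute-force closure oracle),
so the result does not depend on processing order.  Fragments never
merge across target sequences or strands: a fragment must be drawable as
one contiguous block on one track.

**Filtering.**  A fragment is retained iff its target-span extent is
≥ `filtering_pct`/100 × query length, inclusive (the threshold defines
the *minimum* length to be included).  Span extent, not aligned-base
count, is used as the length; aligned bases are exposed separately in
the aggregates.

**Classification.**  The primary fragment is the longest retained one;
ties break by larger aggregate match count, then smaller target start —
an arbitrary but total order, chosen so repeated runs are identical.
Retained fragments overlapping any gene the primary overlaps are
co-gene; the rest are secondary and labeled "(filtered)".  The
full-gene extension takes the hull of the fragment span and the spans of
all genes it overlaps, iterated to a fixpoint so the operation is
idempotent even when the first extension newly reaches another gene.

**Links.**  Only display-adjacent species pairs are linked (that is what
the plot draws, and it bounds cost).  Pairwise alignment blocks are
clipped to both species' displayed fragments (a flag disables clipping),
then chained under the same gap rule applied on *both* sides, which
makes link construction symmetric under exchanging the pair's
query/target roles.  Inverted chains carry `strand_relation=inverted`
and render as crossing ribbons.

**Depth.**  Depth at a reference base counts alignment blocks, not
distinct species, so paralogous alignments contribute multiply — this is
what lets old duplicates exceed single-copy genes in depth.  "Exon" in
the feature classes means CDS-bearing exonic bases, disjoint from the
UTR classes; per-base precedence is exon > 5′UTR > 3′UTR > intron >
intergenic, applied per base when genes overlap.  Box-plot observations
are per-gene class means (per maximal block for intergenic).
Self-alignments of the reference are excluded: only reference-vs-other
records are counted.  The window trend line in plots is an ordinary
smoother and not part of the numeric API.

**Scoring.**  The PSL score is
`matches + repMatches − misMatches − qNumInsert − tNumInsert`, summed
over the members of an assembled fragment (the aggregates are sums, so
the score is linear).  "Normalized to the paralog's length" is read as
division by the annotated gene length, reported per kb; both raw and
normalized values are emitted, and the parent/daughter verdict uses the
normalized mean across partner species by default (configurable),
because raw sums would favour the longer paralog.  Ties and paralogs
with no alignment give an explicit "undetermined".

**Duplication statistics.**  Event tables are consumed as TSV (species,
class, size) rather than recomputed from the alignment archive; the
simulator emits the same schema.  Default size classes start at 50, 100,
250, 500, 1000 and 5000 bp (the last open-ended) and are configurable,
as is the 50-bp exclusion threshold.  The sister-pair comparison is a
paired t-test over per-bin counts; zero-variance differences are
reported as t = 0, p = 1 when identical and t = ±inf, p = 0 flagged
"degenerate" when the difference is a non-zero constant, rather than
crashing or silently returning NaN.

## The simulator

The simulator works at the event/coordinate level and never materializes
sequence; match/mismatch counts are derived from simulated substitution
counts, which keeps fixtures tiny and exactly self-consistent (the depth
conservation identity Σ depth = Σ block sizes holds to the base).

Each ancestral gene (default 100) has 2–5 exons of 150–450 bp separated
by 80–350 bp introns, with 60 bp 5′ and 90 bp 3′ UTRs in transcript
order; genes are laid out with 1.5–3.5 kb intergenic spacers, giving a
~450 kb reference genome for the default five-species tree
`((spA:0.4,spB:0.4):0.3,(spC:0.5,(spD:0.3,spE:0.3):0.2):0.2)`.

Per branch, each gene copy gains Poisson substitutions (rate 0.04 per
base per unit branch length — root-to-leaf ortholog divergence ≈ 6–8 %),
Poisson indels (rate 0.0012, sizes 5–60 bp, placed ≥ min_block+10 bp
apart so that no inter-indel alignment fragment is dropped by the
min-block filter), occasional intron expansions (100–400 bp insertions),
inversions (gene-level strand flips) and losses.  Duplications are
engineered by class so every age class is populated deterministically:
6 founders duplicate at the root ("ancient", both copies inherited by
all species), 4 on the internal branch leading to the reference clade
("old"), 6 on the reference terminal branch ("recent"); tandem daughters
sit adjacent to the parent, dispersed ones at a random position.  A
daughter receives an immediate divergence burst (0.25 per base, an
accelerated-evolution episode confined to the duplication's aftermath);
afterwards it evolves at the normal rate.

**Liftover emulation.**  True copy-vs-copy homologies are broken into
one PSL record per inter-indel run, so consecutive records are separated
by target gaps equal to the simulated insertion sizes (deletions appear
as query-side gaps) — reassembling them is exactly the assembly module's
job.  Fragments shorter than `min_block` (15 bp) are dropped.
Alignability decays with divergence: below a per-base divergence of
d0 = 0.15 every fragment is kept; above it, ~120-bp tiles of each
fragment are kept independently with probability exp(−10·(d − d0)) and
surviving runs are merged back into records.  If every tile of a
homology is lost, one tile anchored at the middle of the longest true
fragment is kept instead: at these divergences a real paralog's
best-conserved patch is still alignable, and parent/daughter inference
presupposes that both copies align somewhere.  This models a
whole-genome aligner recovering only patches of fast-diverging regions,
and it is the mechanism behind the observed depth ordering: ancient
duplicates gain extra (partial) cross-paralog coverage, single-copy
genes align fully, and recent daughters lose much of theirs.

**Ground truth.**  The truth map records every gene's class, all loss
and annotation-gap events, parent/daughter identities of reference-
visible duplications, and `assembly_safe_gap` — the largest observed
inter-record target gap over single-copy ortholog alignments, i.e. the
smallest gap value guaranteed to reassemble each of them into one
fragment.  Losses and annotation gaps are restricted to never-duplicated
genes on non-reference lineages: a lost paralog of a duplicated gene is
observationally indistinguishable from an annotation gap (the other
paralog still aligns), so allowing it would make truth unmatchable by
any detector.  An annotation-gap gene is removed from both the GFF3 and
the orthogroup table (orthogroups are protein-derived upstream, so an
unannotated gene cannot appear in them) while its alignments survive.
Losses and annotation gaps are additionally capped per orthogroup so
that at least one non-reference species keeps an annotated member:
missing-ortholog detection is anchored on cross-species queries and
cannot interrogate an orthogroup that survives only in the reference.

**What the simulator does not model**, and hence what passing tests do
not show about real data: nucleotide-level alignment error, repeats and
low-complexity sequence, segmental duplications spanning several genes,
translocations between chromosomes (each species has one chromosome),
annotation errors other than whole-gene absence, and the idiosyncrasies
of any particular aligner's chaining.  Real-data headline figures
(e.g. genome-wide mean depth in an eleven-species clade) depend on those
factors and on clade size, and are not reproduced at this scale.

## Numerical and design choices

* Threshold comparisons (filtering, gap) are inclusive.
* Primary-fragment ties and orthogroup plot colors (md5 hash of the
  orthogroup id → hue) are deterministic; SVG output is stripped of
  timestamps and hashed with a fixed salt, so identical runs are
  byte-identical.
* Degenerate inputs: empty PSL streams parse to empty lists; a species
  with zero retained fragments is a legal, rendered outcome (it signals
  loss or divergence); an empty fragment set still yields a plot with a
  notice.
* The gap is measured on target coordinates (`gap-axis target`); the
  links stage uses both sides, as noted above.
* Replicate studies in the acceptance script use 40-gene (depth
  ordering) and 30-gene (parent/daughter) clades over 50 seeds — small
  enough to run in seconds, large enough that every gene class is
  populated in every replicate.

## Known limitations

Query regions spanning many genes assemble fragments per species but the
classification is still anchored on a single primary fragment; links are
only built between display-adjacent tracks (no transitive inference
through the reference when a pairwise file is missing); and the paired
t-test treats size-bin counts as paired observations without any
variance-stabilizing transform, matching common practice but sensitive
to heavy-tailed bins.
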