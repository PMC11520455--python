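# syntenica

Synteny-block assembly and visualization across a clade of genomes, built
for the workflow where a multi-genome alignment (e.g. a Progressive
Cactus HAL) has been projected into pairwise PSL files by a liftover
step.  Liftover output is fragmented: one homologous region arrives as
many small alignment records, broken at every indel.  `syntenica`
re-assembles those records into homologous fragments, filters and
classifies them, links neighbouring species, and summarizes conservation
genome-wide — all on coordinates only, with no sequence access needed.

It is aimed at comparative genomicists working with clades of related
genomes (the design target is a *Caenorhabditis*-like clade of ~5–11
species) who want to inspect synteny around a gene, find gene losses and
annotation gaps, distinguish parental from daughter copies of
duplications, and profile conservation by chromosome position, feature
type and gene age.

## The model

Two user parameters control assembly, mirroring the knobs of interactive
synteny browsers:

* **gap value** *g* (default **200 bp**) — two liftover fragments on the
  same target sequence and strand are chained into one assembled
  fragment when the target-side gap between them is ≤ *g*.  Chaining is
  transitive, so an assembled fragment is a maximal chain.
* **filtering percentage** *p* (default **16 %**) — an assembled
  fragment is kept only if its target-span length is ≥ *p*/100 × the
  query length.

Per species the longest retained fragment is the **primary**; retained
fragments hitting the same gene(s) join it in the top panel
(**co-gene**); everything else is **secondary**, displayed below with a
"(filtered)" label — typically paralogous hits.

Other quantities computed:

* **synteny depth** of a reference base — the number of alignment blocks
  from all other species covering it (paralogous alignments count
  multiply); summarized in non-overlapping 20-kb windows, by feature
  class (CDS-bearing exon > 5′UTR > 3′UTR > intron > intergenic,
  precedence applied per base) and by gene class (single-copy vs.
  duplicates of different ages).
* the **PSL score** of a paralog's alignment,
  `matches + repMatches − misMatches − qNumInsert − tNumInsert`,
  normalized per kb of the paralog; the copy with the higher mean score
  across partner species is called the **parent** of a duplication.
* **duplication-event size classes** (events < 50 bp excluded) with a
  paired *t*-test between sister species over the size bins.

A coordinate-level clade simulator (`syntenica.simulate`) evolves genes
down a guide tree — substitutions, indels, tandem/dispersed
duplications, inversions, intron expansions, gene losses, annotation
gaps — and emits exactly the PSL/GFF3/TSV/newick inputs the pipeline
reads, together with a full ground-truth map.  Every pipeline stage is
tested against that truth.

## Worked example

```
$ syntenica simulate --seed 42 --out demo/clade
wrote synthetic clade (5 species, 100 genes) to demo/clade

$ syntenica query spA_g004 --data demo/clade --outdir demo/out
query spA_g004: wrote plot and 3 tables to demo/out

$ head -7 demo/out/fragments.tsv
species t_seq     t_start  t_end  strand  length  n_members  matches  class
spA     spA_chr1  16303    18796  +       2493    0          2493     primary
spB     spB_chr1  16311    18806  +       2495    3          2387     primary
spC     spC_chr1  16363    18880  -       2517    4          2316     primary
spD     spD_chr1  16527    18964  +       2437    6          2244     primary
spE     spE_chr1  16559    19020  +       2461    4          2296     primary
```

Each row is one assembled fragment: `n_members` liftover records were
chained into it (`spD`'s ortholog arrived in 6 pieces), `length` is its
genomic extent and `matches` the aligned identical bases.  `spC` carries
the ortholog on the opposite strand — an inversion — which also shows up
in the links table (`demo/out/links.tsv`) as `inverted` ribbons between
adjacent tracks, and in `demo/out/plot.svg` as crossing ribbons.

Scoring a simulated duplication correctly identifies the parental copy
(the daughter diverged in a burst after duplication, so its alignments
to the other species' single ortholog are shorter and noisier):

```
$ syntenica score --data demo/clade --pair spA_g080,spA_g080b --outdir demo/score
parent: spA_g080 (mean 850.85/kb) | daughter: spA_g080b (mean 67.64/kb)
```

Genome-wide depth:

```
$ syntenica depth --data demo/clade --outdir demo/depth
mean synteny depth 1.353; summaries in demo/depth
```

(1.353 averages over the whole genome including unaligned intergenic
spacers; over gene bodies the single-copy median is ≈ 3.9 of a possible
4 in this five-species clade — see `demo/depth/gene_classes.tsv`.)

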