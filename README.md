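# genecycle

Gene gain and loss shape both proteomes and the interaction networks
they form.  `genecycle` implements an end-to-end analysis of the gene
"life cycle" across a clade of genomes — written for ascomycete fungi
viewed from *S. cerevisiae*, but generic over any rooted species tree
with a designated focal species.  It is aimed at molecular
evolution / systems-biology researchers who have an orthology map, a
species tree and per-gene network/expression data and want to ask how a
gene's evolutionary stage relates to its place in the cell's networks.

## What it computes

Given an orthogroup membership table, a rooted tree with a pairwise
distance matrix (e.g. median Ka), and per-gene feature files, the
pipeline:

1. **Fits relative branch lengths** by constrained least squares on the
   fixed topology (exact on additive matrices).
2. **Infers gain and loss events per gene by Dollo parsimony** — a gene
   is gained at most once and losses are irreversible, so the gain
   branch is the branch above the MRCA of the carrier species (or
   "pre-root" if any outgroup species carries it) and the losses are the
   maximal all-absent clades inside the gain clade.  The outgroup is the
   union of the two root-most clades off the root-to-focal path.
3. **Classifies life stages**: `core`, `distant_loss` / `local_loss`
   (is the closest loss lineage inside the clade below a threshold
   split, e.g. with *K. waltii*?), `ancient_gain` / `recent_gain`,
   `focal_specific`, `excluded`.
4. **Handles duplications**: duplicate families from the orthology map
   (≥ 2 focal genes per orthogroup), slowest-evolving-copy selection via
   similarity to the closest single-copy witness, pre/at/post-WGD
   timing, and removal of "gained" genes that are sequence-similar
   (e < 1e-4) to an older gene.
5. **Quantifies loss propensity** (independent loss events ÷ branch
   length on which loss was possible) and compares event rates before
   vs after the whole-genome duplication.
6. **Runs the statistical battery**: per-stage medians with
   bootstrapped SEs (100 resamples), Wilcoxon rank-sum comparisons
   (exact for small samples), Fisher exact TF-enrichment tables, a
   six-feature logistic model of local gene loss with drop-one partial
   tests and an R² defined as the squared correlation of fitted
   probabilities with outcomes, and the network-integration ordering
   test: degree ratios of young vs old genes across the regulatory,
   kinase, genetic and PPI networks, compared against the experimental
   network-rewiring order (an exact match of 4 networks has
   p = 1/4! ≈ 0.042).
7. **Re-examines loss locality from a second species' frame**
   (`crossspecies_view`), testing whether marginalization of
   soon-to-be-lost genes is lineage-specific.

A first-class synthetic-data generator (`genecycle.synthetic_data`)
emulates every input with known ground truth, so the whole pipeline is
testable end to end; see `docs/methods.md` for the model, the generator
conditions and their rationale.

## Worked example

```sh
genecycle simulate --out demo --seed 2 --n-species 12 --n-genes 600
genecycle run --in demo --out demo_out --seed 2
cat demo_out/report.txt
```

prints (abridged):

```
gene life-cycle analysis report
===============================
focal species: sp01
outgroup: sp02,sp03,sp04,sp05
genes in: 648  classified: 614  excluded: 34
life-stage counts: core=420, distant_loss=92, local_loss=11, ancient_gain=70, recent_gain=10, focal_specific=11, excluded=34
total loss events: 125
duplicate families: 24

network integration (degree ratio, young/old): regulatory=1.687, kinase=0.928, genetic=0.560, ppi=0.425
integration ordering p = 0.0417
local-loss logistic model: n=523, R^2=0.1907, direction=--+-+-
```

Reading this: of 648 focal genes, 614 were classifiable (34 had no
ortholog anywhere or were gains explained by duplication).  The degree
ratios say anciently gained genes have already reached 1.69× the mean
regulatory in-degree of the oldest genes but only 0.43× their mean PPI
degree — the four networks rank exactly in the reference rewiring order,
which has probability 1/24 ≈ 0.042 under a random ordering.  The
logistic model of local loss assigns the direction pattern
`--+-+-` (fewer PPI and genetic partners, more regulators, lower
expression, more variable expression, less often essential) and its
fitted probabilities correlate with observed local loss at R² = 0.19.
Per-table outputs (`classification.tsv`, `branch_events.tsv`,
`stage_medians.tsv`, `tf_enrichment.tsv`, `wgd_rates.tsv`,
`loss_model.tsv`, `integration.tsv`, `families.tsv`,
`crossspecies.tsv`) land next to the report.

The same analyses run on real data by pointing `--in` at a directory
with the documented file formats (Newick tree; square distance TSV;
`orthogroups.tsv` with orthogroup_id/species/gene_id; 2-column edge
lists; TF→target table; gene × condition expression matrix; read
counts; essential/TF flags; BLAST-style hit table).  Genome-wide
published counts for *S. cerevisiae* depend on the external orthology
database and curated feature tables and are therefore not reproducible
offline; given such a table, `pipeline.summarize_classification`
recomputes the headline counts from it directly.

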