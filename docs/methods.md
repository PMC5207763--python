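# Methods

## The model

`genecycle` analyses the evolutionary life cycle of the protein-coding
genes of one focal species against a rooted species tree.  The unit of
analysis is the orthogroup: a set of genes across species descended from
a single ancestral gene.  Presence/absence of each orthogroup across the
tree is interpreted under the Dollo model — a gene family is gained at
most once and every loss is irreversible — so the history of a gene
present in the focal species is fully determined by its leaf pattern:

* **Gain branch.**  If any outgroup species carries an ortholog the gene
  predates the ingroup ("oldest"; the gain is `pre-root` and not dated
  further).  Otherwise the gain sits on the branch immediately above the
  most recent common ancestor (MRCA) of the carrier species, which
  always lies on the root-to-focal path.
* **Loss events.**  The maximal all-absent clades inside the gain clade,
  one event per clade.  This is the unique minimum-event irreversible
  reconstruction given the gain placement (placing the gain any higher
  only adds losses), which the test suite verifies against brute-force
  enumeration of all single-gain histories on trees of up to seven
  leaves.
* **Outgroup convention.**  The outgroup is the union of the two
  root-most clades hanging off the root-to-focal path.  Absence confined
  to outgroup clades is ignored — with only two deep outgroup lineages it
  cannot be distinguished from sparse sampling — and, symmetrically, the
  outgroup contributes no loss-opportunity branch length.

Life stages partition focal genes: `core` (oldest, never lost),
`distant_loss` / `local_loss` (oldest, lost somewhere; *local* iff some
loss lineage split from the focal lineage strictly below a configurable
threshold node — the split with *K. waltii* in the intended
application), `ancient_gain` / `recent_gain` (dated gains above/below
the same threshold), `focal_specific` (present only in the focal
species), and `excluded` (no ortholog anywhere, or a "gained" gene whose
sequence similarity to an older gene, e-value < 1e-4, reveals a
duplication the orthology map missed).  Losses on gained genes are
recorded but never drive staging, so loss-associated properties are not
confounded with gene age.

Note one deliberate reading: a lost gene is classified by the
*topological* position of its closest loss (which side of the threshold
node the lost lineage split from), not by patristic distance.  The two
readings coincide except under extreme branch-length asymmetry.

## Branch lengths

Relative branch lengths are fit to the fixed topology from a symmetric
matrix of pairwise species distances (median Ka over slowly evolving
proteins in the intended application; computing Ka itself is out of
scope — the matrix is an input file).  The fit minimises the squared
error between patristic and observed leaf-pair distances: an ordinary
least-squares problem on the path-incidence matrix, solved by
minimum-norm `lstsq`, with a nonnegative (NNLS) refit plus warning
whenever the unconstrained solution goes negative (triangle-violating
matrices).  On an additive matrix the residual is exactly zero and the
three-point formula is reproduced.  The two root-adjacent branches of a
rooted binary tree are constrained only through their sum; the
minimum-norm solution splits the sum equally, and the synthetic-tree
generator adopts the same convention, so round-trips recover every
branch length.

## Loss propensity and event rates

A gene's loss propensity is its number of independent loss events
divided by the branch length on which loss was possible: all branches
off the root-to-focal path inside the gain clade, excluding outgroup
subtrees, excluding everything below a loss event (the gene is already
gone there) but including the loss branch itself.  The quantity is
invariant under uniform rescaling of the tree, so only relative branch
lengths matter.

Event-rate comparisons around the whole-genome duplication (WGD) divide
loss events by off-path branch length, partitioned by whether the loss
branch descends from the WGD node, and gain events by focal-path length
above vs below it.  The default test is an exact two-sided binomial test
of the observed event split against the length split; a Fisher 2×2
variant (gains vs losses × pre/post) is available behind a flag.  The
exact construction behind the published Fisher figure is not recoverable
from its description; this one is ours and is stated as such.

## Duplications

A duplicate family is an orthogroup with ≥ 2 focal genes and ≥ 1
non-focal witness.  The slowest-evolving copy is the member with the
highest percent identity to the ortholog in the closest species that is
single-copy for the orthogroup (patristic distance to the focal species;
lexicographic tie-breaks).  Timing is read off the MRCA of the species
visibly carrying ≥ 2 copies, classified as before / at / after the WGD
branch; a duplication visible only in the focal species is `post_wgd` by
convention.  When deep copies have been lost the visible MRCA can sit
below the true duplication point — the tests therefore assert exact
recovery on loss-free families only.

## Statistics

* **Fisher 2×2**: two-sided p sums hypergeometric point probabilities no
  larger than the observed table's (the R `fisher.test` convention);
  effect is the sample odds ratio.
* **Wilcoxon rank-sum**: exact by enumeration of all rank splits when
  n ≤ 12 (midranks, so ties are handled by enumeration rather than
  approximation), otherwise normal approximation with tie and continuity
  corrections.
* **Medians** are summarised everywhere with a bootstrapped standard
  error (100 seeded resamples by default).  Note that the bootstrap SE
  of a median for a single sample fluctuates on the slow n^(-1/4) scale;
  it matches the asymptotic 1.2533·σ/√n only on average over samples,
  which is how the test suite checks it.
* **Local-loss model**: logistic regression of "lost locally" (vs all
  other oldest genes) on six features — PPI degree, genetic-interaction
  degree, regulatory in-degree, mRNA expression, expression spread,
  essentiality.  Features are standardized internally; coefficients are
  reported on the input scale.  Per-feature partial p-values compare the
  full model with the drop-one model, by likelihood-ratio chi-square by
  default (an F-statistic on the deviance is available, since "partial
  F-test" is not standard for logistic models).  Model fit is reported
  as the squared Pearson correlation between fitted probabilities and
  the 0/1 outcome.  Perfect separation falls back to a tiny ridge
  (λ = 1e-6) with a warning; constant or collinear features are dropped
  with a warning.  Raw p-values are reported; Benjamini–Hochberg
  adjustment exists but is off by default.
* **Network integration**: the mean degree of anciently gained genes
  over the mean degree of the oldest genes, per network type (ratio, not
  difference, to normalise out edge density).  The observed ranking of
  the four networks is compared with the reference rewiring-rate order
  (regulatory > kinase > genetic > PPI): an exact match has probability
  1/4! ≈ 0.042 under uniform orderings; otherwise a concordant-pairs
  tail probability is reported.

## The synthetic-data generator

The generator produces every input file the pipeline consumes, with
known ground truth, from one seeded configuration.  Its defaults are the
study conditions: 23 species, ~4,600 focal genes of which 83% predate
the ingroup, a WGD branch just below the local threshold with a 4× loss
rate and a 1/5.3 gain weight downstream, a marginalized quarter of genes
with 3× loss rate, duplicate families at 5% of oldest genes, 84/880 of
gains flagged as missed duplications, and stage effects encoding the
qualitative findings (lineage-specific genes: more regulators, more
variable and lower expression, fewer physical/genetic partners, TF
fractions 1.2 / 2.6 / 4.4 / 4.5% for core / lost / gained / duplicated).

Specific modelling choices:

* **Tree shape.**  A backbone from root to the focal leaf with one random
  side clade per backbone node (exponential branch lengths, mean 0.12
  substitutions/site).  A uniformly random join process would place the
  focal leaf shallow and let the two-clade outgroup rule swallow most of
  the tree; the backbone shape reproduces the deep nesting of the focal
  species in the intended application.  The local threshold defaults to
  the deepest focal-path node whose clade still holds ~30% of species.
* **Histories.**  A gain branch (pre-root for oldest genes, else sampled
  along the focal path ∝ branch length × WGD gain deflation), then
  independent per-branch losses with probability 1 − exp(−rate·length);
  a lost lineage stays lost unless `allow_regain` is set.  Survival of
  the focal lineage is imposed by never firing losses on the focal path
  (exact conditioning, since branches are independent).  With regain
  disabled the generator resamples the rare gene whose realized history
  is not parsimony-identifiable (both children of a surviving node lost,
  gain clade pruned at its root, or an oldest gene wiped from the entire
  outgroup); the recorded events are then exactly the canonical Dollo
  reconstruction, which is what makes the generator/inference identity
  test meaningful.  This canonicality is a property of the generator,
  not of the inference.
* **Features.**  Degrees are negative binomial (dispersion 2) with
  stage-multiplied means; the emitted edge lists are constructed so the
  distinct-partner degree computed from them equals the sampled degree
  exactly (partners drawn without replacement from auxiliary pools, with
  kinase partners drawn from the emitted kinase set).  Expression
  intensities are 10^Normal(μ_g, σ_g) across 300 conditions with
  σ_g ~ Gamma, so the computed log10 SD matches the stage-scaled spread
  in distribution; rich-media expression is log(reads+1) of negative
  binomial counts.  Kinase-degree means are *not* deflated in lost genes:
  lost genes dominate the "old" group, and deflating them there would
  invert the intended kinase-vs-regulatory integration ordering.
* **Cross-species frame.**  A second "focal" species is chosen inside a
  distant non-outgroup clade of ≥ 3 species where possible; its own
  expression/interaction files are generated with marginalization keyed
  only to losses near that species (multiplier 0.55), so the
  lineage-specificity of marginalization is a testable generative fact.
* **What it does not emulate.**  Real orthology-inference errors,
  correlated loss across neighbouring branches, gene conversion between
  duplicates, expression batch structure, or any sequence-level signal
  (similarity hits are generated at the score level).  Passing tests
  therefore show the pipeline is correct under the stated model, not
  that the model captures every property of real genome data.

## Problem sizes

Tests run the generator at 10–23 species and 250–10,000 genes; the
reconstruction sweep enumerates all rooted topologies to five leaves and
seeded samples of 120 topologies at six and seven leaves, against an
oracle that enumerates every internal-state assignment.  The acceptance
script runs the full default-scale bundle (23 species, ~4,600 genes, 300
conditions) end to end.  These sizes were chosen so the whole suite
completes in well under a minute while every code path, including the
cross-species view and the golden-file summary, is exercised at a scale
where the statistical contrasts are detectable.

## Known limitations

* Genome-wide counts of the intended application (core/lost/gained gene
  totals, WGD rate folds, the R² of the local-loss model) depend on the
  external orthology database and curated feature tables and cannot be
  reproduced from this repository alone; given such a table, the
  golden-file entry points (`pipeline.summarize_classification`, a
  loss-model refit from TSV) reproduce them mechanically.
* The measured WGD loss fold recovers the generative rate multiplier
  only up to saturation of P(≥1 loss) on long branches, so it varies by
  tree (~2.8–4.2 around the generative 4×).
* Duplication timing is inferred from visible copy sharing and has no
  access to a curated ohnolog list (an override file can supply one).
* With `allow_regain` enabled the Dollo reconstruction undercounts
  events by design; the inferred gain never moves above the true gain.
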