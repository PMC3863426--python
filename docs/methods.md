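# Methods

This note documents the models, rules and numerical conventions the package
implements, the design choices made where a convention had to be fixed, and
what the synthetic world does and does not establish.

## Duplication-age assignment

A gene-family tree is a rooted tree whose internal nodes are annotated with
an event type (duplication or speciation), the taxon the reconciliation
assigned to the event, and — for duplications — a consistency score in
[0, 1] measuring how well the duplication is supported by the species
overlap of its two subtrees. The NHX dialect read and written here uses
`D=Y|N`, `S=<taxon>`, `DCS=<float>`; unknown tags are ignored with a
warning, and an internal node with no NHX comment at all is accepted as an
unannotated speciation node (so bare Newick is valid input).

For each focal-species leaf the assigner walks leaf → root and inspects
duplication nodes in order:

* `score > threshold` (default 0.3): accept. The gene is a protein-coding
  duplicated gene (PDG); its age class is the node's taxon resolved
  against the timeline (collapse aliases first, e.g. Euarchontoglires →
  Eutheria). If the taxon is older than the oldest timeline class the gene
  is instead a **singleton**: it has no duplication origin within the
  analyzed era.
* `score == 0`: the duplication is treated as a reconstruction artifact.
  The walk continues to the next duplication node toward the root —
  speciation nodes are never age evidence, so "the previous node" is read
  as the next duplication on the root path.
* `0 < score <= threshold`: the call is unclear; the gene is
  **unassigned** and the walk stops.
* Exhausted path: **singleton**.

Boundary choices, fixed deliberately: acceptance is *strict* (`> 0.3`; a
score of exactly 0.3 voids the call), and the skip rule applies only to
scores of exactly 0. Statuses are mutually exclusive and exhaustive; a gene
appearing in two trees is a data error, since family trees partition genes.

Timelines ship as YAML: 14 human classes (Bilateria, Coelomata, Chordata,
Euteleostomi, Tetrapoda, Amniota, Mammalia, Theria, Eutheria, Simiiformes,
Catarrhini, Hominidae, HomoPanGorilla, Homo sapiens) and 13 mouse classes
(the same through Eutheria, then Glires, Rodentia, Murinae, Mus musculus),
both collapsing Euarchontoglires onto Eutheria because gene trees are
frequently inconsistent with the species phylogeny at that level.

## CNV calling

A gene is copy-number variable when at least `min_individuals` (default 2)
individuals carry ≥ `gain_threshold` (default 4) copies, **or** at least
`min_individuals` carry < `loss_threshold` (default 2) copies. The two
counts are evaluated independently — gains and losses need not come from
distinct individuals — and copy number 0 counts as a loss. Exclusions are
applied before calling: genes strictly shorter than 1 kb (length = end −
start on the provided 0-based half-open coordinates; exactly 1,000 bp is
kept) and, by default, non-autosomal genes. Setting `loss_threshold = 0`
gives a gains-only call, which is provably a subset of the default call.

## Replication-timing ranks

Within each sample, probe log-ratios are replaced by midranks oriented so
rank 1 is earliest; the orientation is governed by a declared
`sign_convention` (default `higher_is_earlier`, the usual early/late log2
ratio — arrays differ, so this is an explicit input property rather than a
guess). Each probe then gets the median of its per-sample ranks (mean of
the two central values for even sample counts). Each gene takes the median
rank of the probe nearest its center — `floor((start + end) / 2)` —
with ties between equidistant probes resolved to the lower coordinate, and
is dropped from RT analyses when the nearest probe is strictly further
than 10 kb (exactly 10 kb is kept). Genes retaining a value are re-ranked
(midranks) into the order of replication. Because only ranks cross sample
boundaries, any per-sample monotone transformation of the raw log-ratios
is a no-op downstream; no quantile normalization is added.

## Region stratification

Distances are measured from the gene center. Distance to the centromere is
the distance to the nearest contained position of the interval
[cen_start, cen_end) (0 inside); distance to the telomere is
min(center, length − center). A gene is pericentromeric when the
centromere distance is ≤ the window (default 5 Mb, boundary inclusive),
else subtelomeric when the telomere distance is, else interstitial.
Pericentromeric wins when both windows cover a gene; this precedence keeps
the partition well defined and makes the first megabases of an acrocentric
chromosome (centromere abutting position 0) pericentromeric rather than
subtelomeric.

## Test battery

* Chi-squared independence: Pearson statistic, no continuity correction;
  2×2 tables with an expected cell < 5 report Fisher's exact p alongside.
* Two-proportion comparison: the 2×2 chi-squared; effect = p1 − p2.
* Wilcoxon rank-sum: exact null distribution when both groups are ≤ 20 and
  tie-free, otherwise the normal approximation with tie correction; effect
  is the rank-biserial correlation. Complete overlap (zero variance) is
  p = 1, not an error.
* Spearman: Pearson correlation of midranks, two-sided t-approximation
  (df = n − 2), optional permutation p for small n. Age enters as the
  ordinal phylostratum index (1 = oldest), so a positive ρ means younger
  genes replicate later.
* Fold enrichment: (region rate) / (genome-wide rate), p from the 2×2
  chi-squared of region vs rest-of-genome.

Raw p-values are reported without multiple-testing correction (the
standard presentation for this analysis style); the serialized results
carry the battery size so a reader can correct post hoc.

The young/old split of PDGs defaults to the oldest lineage-specific class —
Simiiformes for human ("duplicated since the primate ancestor"), Glires
for mouse — with genes in that class or younger counted as young. The
boundary is configurable because the phrase "after primates evolved" could
also be read to include Eutheria-era nodes on the primate stem.

## Synthetic world

The generator emulates the *derived* quantities the pipeline consumes, not
the processes that produce them (no sequence evolution, read depth, or
array hybridization). Its defaults are the package's stated world:

* **Genome**: 4 autosomes of 100 Mb (optionally plus a chrX for exclusion
  tests), metacentric 2 Mb centromeres; 10,000 genes of 2–20 kb placed
  uniformly within disjoint slots (this guarantees non-overlap and a
  capacity error when genes cannot fit, at the cost of exact uniformity of
  inter-gene gaps).
* **Ages**: uniform mass over the age classes plus a 28% singleton atom —
  real age spectra are old-heavy, but a uniform spread gives every class
  comparable power in recovery tests; the singleton fraction matches the
  roughly 1:2.6 singleton:duplicate ratio of mammalian catalogues.
* **Trees**: a caterpillar backbone of speciation nodes following the
  timeline (assignment only inspects the focal leaf's root path, so
  topology elsewhere is free), with each duplicate hanging below a
  duplication node spliced at its planted class. The duplicate's partner
  copy is labelled as a non-focal placeholder species so the focal gene
  set matches the annotation exactly. Consistency scores default to
  Uniform(0.5, 1) — all acceptable — and `decoy_zero_prob` optionally
  inserts zero-score artifact duplications at younger classes, which a
  correct assigner must skip.
* **Copy numbers**: 159 individuals, diploid baseline. Planted CNV genes
  (age-dependent probability: 3% for old classes and singletons, rising
  0.4 → 0.7 over the five youngest classes) receive a gain (4–6 copies) or
  loss (0–1) in 2 + Binomial(n−2, 0.15) individuals; other genes stay in
  {2, 3} with at most one stray individual, so they sit near but below the
  calling threshold.
* **RT probes**: tiles every 5 kb, four samples. The latent value of a
  probe is `baseline − rt_age_effect × (age_index − 1)` of the nearest
  gene (default effect 0.5 per class step), singletons behaving like the
  oldest class; each sample adds i.i.d. N(0, 1) noise. CNV status has no
  *direct* RT effect: the young-CNV-replicates-later pattern emerges
  purely from composition (younger classes are both more CNV-prone and
  later-replicating), which is exactly what makes the old-PDG comparison a
  true null.

Determinism: every generator draws from its own child stream of the config
seed, so each layer — and the full written dataset — is bit-reproducible.

A green end-to-end test therefore establishes that the pipeline recovers
planted marginal structure and produces calibrated nulls; it does **not**
establish effect sizes comparable to real genomes (the synthetic age→RT
correlation is ρ ≈ 0.97, far above anything real data shows), spatial
clustering of young duplicates near centromeres (gene positions are
age-independent, so region enrichment tests are null here), or robustness
to array artifacts, mappability bias, or incomplete tree sampling.

## Known limitations

* The CNV model plants per-gene labels, not shared CNV regions spanning
  several genes; linkage between neighbouring genes' calls is absent.
* The uniform-slot gene placement slightly regularizes inter-gene
  distances relative to a Poisson process.
* Probe latent values switch sharply at gene-territory midpoints rather
  than following smooth replication-domain profiles.
* The exact Wilcoxon path is limited to tie-free small samples; with ties
  the normal approximation is used at any n.
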