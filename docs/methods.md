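# Methods

This note documents the models, parameter choices, numerical details
and known limitations of `mminet`. Nothing here states an empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Record model and parsing rules

A metabolite record carries an accession, a display name, a non-empty
subset of {feces, serum, CSF} biospecimen locations, a non-empty subset
of {bacteria, fungi} source kingdoms, and a possibly empty set of
source-taxon names. Kingdom classification is a case-insensitive
substring match on the tokens "bacteria"/"fungi" in the disposition's
kingdom label; records matching neither are dropped and counted.
Records with no recognized biofluid are likewise dropped with a
warning, preserving the non-empty-biofluid invariant. Taxon names are
normalized by trimming, collapsing internal whitespace and
capitalizing the first letter; genus-only and genus+species strings
remain distinct entities, since real curation mixes genera, species
and strains and conflating them would silently merge repertoires.
Metabolites whose disposition names a kingdom but no organism are
attributed to the sentinel entities "Unnamed bacteria" / "Unnamed
fungi"; sentinels participate in the layered network but are excluded
from taxon-level projections, clustering and the commonality graph,
which analyse named organisms only.

Merging per-biofluid collections unions biofluids, kingdoms and source
taxa per accession; conflicting display names keep the first seen with
a warning. The id-keyed merge is one defensible choice; name-keyed
reconciliation across accessions is deliberately not attempted.

## Over-representation and term grouping

The query (metabolite-target genes, or a disease gene set, or viral
targets) is intersected with the gene universe before testing. The
universe defaults to the union of all term gene sets, and can be
supplied explicitly (the pipeline's `universe` input; the synthetic
bundle exports its full gene universe because a GMT file cannot carry
it). Each term is scored by the hypergeometric upper tail
`P(X >= k)`; terms with zero overlap receive p = 1 exactly.
Benjamini–Hochberg step-up adjustment (statsmodels) is applied across
all terms of the annotation, and significance means adjusted p <= alpha
(default 0.05).

Significant terms are grouped by Cohen's kappa on the 2×2 contingency
of query-gene membership. The default threshold 0.4 is the convention
of interactive enrichment tools; groups are the connected components
of the kappa graph — a hard partition, deliberately simpler than
iterative group-merging schemes, and recorded as an approximation.
When chance agreement is exactly 1 (both membership vectors constant
and identical) kappa is defined as 1. Each group's leading term has
the smallest adjusted p, with ties broken by larger term size then
lexicographic term id.

## Layered networks

The MMI network is a simple undirected graph with typed nodes (taxon,
metabolite, gene, term) and typed edges whose endpoint types are
validated at insertion. A metabolite links to a significant term when
any of its target genes is a query gene annotated to that term — an
existential, unweighted rule. Metabolites with no term edge and taxa
with no surviving metabolite are pruned; because pruning is monotone
(removing a metabolite can only remove taxa, never metabolites), the
fixed point is independent of order. Term–term edges are the kappa
edges among significant terms. Disease overlays reuse the same
container with gene nodes restricted to intersection nodes (disease
genes targeted by at least one metabolite), gene–term edges from the
disease's own enrichment, and gene–gene edges from the confidence-
filtered intra-set PPIs.

Projections are entity → feature-set maps: metabolite→term and
taxon→metabolite read edges directly; taxon→term composes the two
steps (union over the taxon's metabolites), which provably equals the
boolean product of the two incidence matrices — asserted by an oracle
test.

## Similarity clustering

Binary incidence rows are compared by Jaccard distance. All four
candidate linkages (average, complete, single, ward) are fitted on the
condensed distances and the linkage with the highest Pearson
correlation between cophenetic and input distances wins; NaN
correlations (constant distances) lose to any finite value, and ties
resolve by candidate order. Trees are cut with `cut_tree` to exactly
`k` clusters (or by merge height on request). Merge order inside scipy
is deterministic for a fixed row order, and entities are always sorted
before matrix construction, so runs are reproducible. The joint
virus–taxon clustering appends the virus as an all-ones row over the
common terms; the requested `k` is capped at the number of distinct
coverage profiles so that profiles identical to the virus are never
split away from it by an over-specified cut.

## Commonality graph

Two taxa are joined when their metabolite sets intersect; the weight
is the intersection size and the default minimum is 1 shared
metabolite (configurable). Strength is the weighted degree; the
handshake identity (sum of strengths = twice the total weight) and the
equivalence of the articulation set with the node-deletion oracle are
asserted on random graphs. Articulation points come from linear-time
biconnectivity (networkx).

## Rewiring

Two networks are compared by set algebra on node ids and canonical
edges (sorted endpoint pair plus edge type; attributes ignored). The
scalar score `1 - |common| / |union|` over edges is this package's own
summary of wiring divergence — 0 for identical edge sets, 1 for
disjoint ones, and 0 by convention when both networks are edgeless. It
is symmetric and its class counts satisfy the conservation identities
tested on random pairs.

## Synthetic universe

The generator is the package's study design in miniature; its defaults
are the conditions under which recovery is tested.

* **Scale.** 60 taxa, 90 metabolites, 300 genes, 30 terms, 4 diseases
  of 40 genes, 20 viral proteins over four strain labels — small
  enough that every stage runs in seconds, large enough that the
  hypergeometric tail and the cluster geometry are non-trivial.
* **Clusters.** The metabolite pool is split into disjoint per-cluster
  cores of `repertoire_size` (default 12); every taxon carries its
  cluster's core, so within-cluster Jaccard distance is 0 and
  between-cluster distance is 1 at zero noise — the clustering stage's
  expected answer is analytic. Noise swaps each membership
  independently (probability `noise_rate`) with a metabolite outside
  the repertoire, keeping repertoire sizes constant.
* **Articulation taxon.** One extra taxon carries half of the first
  two clusters' cores, making it the only connection between two
  otherwise metabolite-disjoint cliques in the commonality graph. It
  has no cluster label; recovery is scored on the labelled taxa.
* **Terms.** Planted terms draw 90% of their genes from the realized
  query (metabolite-target genes, themselves drawn from a pool of 30%
  of the universe); the remaining terms draw uniformly from the whole
  universe and are therefore *exactly* null under the hypergeometric
  model — the empirical false-discovery rate among them is a
  calibration check, not an approximation.
* **Diseases and virus.** A configured fraction of each disease's
  genes comes from the query — drawn preferentially from planted-term
  genes so disease enrichment carries recoverable signal, mirroring
  the premise that disease genetics overlaps immune-relevant targets.
  The planted per-disease intersection is recorded in the ground
  truth. Viral targets draw their disease-derived share from the same
  immune-relevant genes; strains are labels on viral proteins of a
  single virus entity.
* **Determinism.** All randomness flows from one `numpy` generator
  seeded by `config.seed`; every set is materialized in sorted order
  before random draws or file writes, so two runs at one seed are
  byte-identical.

What the generator does **not** emulate: realistic metabolic
chemistry, taxonomic plausibility of names, database curation biases,
correlated annotation structure (GO ancestry), or scale-free PPI
topology. Passing recovery tests therefore demonstrates correctness of
the algorithms under the planted model, not performance on real
curation noise.

## Problem sizes used in checks

Cluster recovery runs at 30 taxa / 60 metabolites / 3 clusters
(noiseless, and 20 seeds at 5% noise); enrichment calibration pools
100 universes at 12 taxa / 150 genes / 20 terms (4 planted);
determinism runs the full pipeline twice at 24 taxa / 3 diseases.
These sizes were chosen so the whole verification suite completes in
seconds while keeping every statistic away from degenerate regimes.

## Known limitations

* ClueGO-style iterative group merging, GO DAG propagation and
  identifier translation are out of scope; term grouping is a single
  hard partition.
* The rewiring score is a plain edge-set Jaccard distance, not a
  variance-based multi-network rewiring statistic.
* The kingdom filter counts a dual-kingdom record under both kingdoms,
  so kingdom-filtered totals overlap by the size of the "both" class.
* `cut_tree` guarantees exactly `k` labels only when the forest has at
  least `k` distinct merge heights below the cut; with heavily tied
  distances the assignment among identical profiles is determined by
  merge order (deterministic, but arbitrary), which is why the joint
  virus clustering caps `k` by distinct profiles.
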