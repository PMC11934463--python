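# Methods

## The model

termwalk treats a gene-set collection as a bipartite graph. A collection
contributes a gene set `G = {g_1..g_m}` and a term set `T = {t_1..t_n}`
(a *term* is any named gene set: a pathway, GO category, phenotype, or
expression signature). Genes are indexed `0..m-1` in first-appearance
order, terms `m..m+n-1` in file order, and one undirected edge joins a
gene to every term that contains it, so `|V| = m + n` and
`|E| = Σ_t |genes(t)|`. The index order is fixed so that identical inputs
produce identical graphs; genes that appear in no term never enter the
node universe (they would be isolated, and a walk from an isolated node is
undefined).

Node vectors come from node2vec: second-order biased random walks followed
by skip-gram with negative sampling. Stepping from the current node after
arriving from `v`, a candidate `x` receives unnormalized weight

    1/p   if x = v           (return)
    1     if d(v, x) = 1     (common neighbor)
    1/q   otherwise          (exploration, d(v, x) = 2)

normalized over the current node's neighbors. On a bipartite graph the
middle branch is unreachable for `x != v` — `v` and `x` both lie opposite
the current node — so `p` and `q` alone shape the walks: small `q` pushes
outward (DFS-like), large `q` keeps walks local (BFS-like). The first step
of each walk has no predecessor and is taken uniformly; the walk kernel
nevertheless implements the general three-case rule (candidate adjacency is
checked by binary search), so it is correct on non-bipartite graphs too.

Term pairs are then scored three ways: the Jaccard index
`J(A, B) = |A ∩ B| / |A ∪ B|` of their gene sets; the hypergeometric
upper-tail probability of observing at least the shared gene count when
`|B|` genes are drawn from the gene universe (screened at p < 0.05, raw —
a Benjamini–Hochberg column is available but off by default, matching the
screening convention); and the euclidean distance between their embedding
vectors. Distances are min–max normalized to [0, 1] globally over all
pairs of a run, and the "closest pairs" are those at or below the value of
the `ceil(0.05·N)`-th smallest distance (ties included). A minimum
spanning tree over the normalized distance matrix sketches the global
backbone of term relationships.

## Training details

Skip-gram pairs are every (center, context) combination within
`context_size` positions inside a walk (a fixed window, not the shrinking
window some implementations sample — fixed is simpler and deterministic).
Each positive update is accompanied by `negative_samples` negatives drawn
from the corpus unigram distribution raised to 3/4, the de-facto standard
noise distribution, materialized as a 2^17-slot sampling table filled by
largest-remainder apportionment. The optimizer is plain SGD with a linear
learning-rate decay from 0.025 to 1e-4 over all scheduled updates; vectors
are initialized uniformly in ±0.5/d (center matrix) and zero (context
matrix), and the center matrix is the embedding. Walks and updates run in
seeded single-threaded numba kernels, so a fixed seed reproduces the
embedding bit for bit; sub-seeds for shuffling, initialization, walking
and sampling are derived from the configured seed through
`numpy.random.SeedSequence`.

Defaults: d = 64, walk length 20, 10 walks per node, p = q = 1, context
10, 5 negatives, 40 epochs. The dimensionality follows the preferred
64-dimensional space (32 is the grid alternative); the remaining values
are the grid midpoints, a documented choice since no single winning grid
point is fixed by the method. The full search grid is the Cartesian
product of d ∈ {32, 64}, walk length ∈ {10, 20, 30}, p, q ∈ {0.25, 0.5,
1, 2, 4}, context ∈ {10, 20}, negatives ∈ {1, 5, 10}, walks per node
∈ {10, 20, 30} — 2700 configurations, 40 epochs each. Running all 2700 is
a week-scale job; `termwalk grid --limit` evaluates a prefix.

## Model selection

Embeddings are compared without labels: k-means (seeded, 10 restarts)
partitions the term vectors, and two internal validation metrics score the
partition — the Silhouette score
`S = (1/n) Σ_i (b_i − a_i)/max(a_i, b_i)` (higher is better; singleton
clusters score 0 by convention) and the Davies–Bouldin score
`DB = (1/k) Σ_i max_{j≠i} (σ_i + σ_j)/d(c_i, c_j)` (lower is better;
coincident centroids are an error, not an infinity). Both use euclidean
distance, matching the embedding space. Configurations rank by Silhouette
descending, Davies–Bouldin ascending as tiebreak, then a fixed field
order, so selection is independent of input order. Term vectors (not gene
vectors) are clustered by default: terms are the objects whose
relationships the pipeline reports, and on modular collections the term
partition is the planted signal; `nodes="all"` is available. The cluster
count is a parameter — the validation metrics are comparable across
embeddings only at a common k, and when the true module count is unknown a
small sweep (e.g. k ∈ {5, 10, 20}) with the best Silhouette reported is
the pragmatic default.

## Cross-species projection

A second-species collection enters the host space in two steps. First,
ortholog conversion: each gene is replaced by *all* of its ortholog
targets from a static two-column table (one-to-many fans out; many-to-one
collapses by set semantics); unmapped genes are dropped, and terms whose
converted set is empty are dropped and listed. The per-term attrition
report (n_genes, n_mapped, coverage, status) is a mandatory output —
ortholog mapping typically loses over half the source genome, and the
user must see that attrition. Second, placement, by one of two strategies,
both leaving the host matrix bitwise unchanged:

- `neighbor_mean` (default): the term vector is the arithmetic mean of
  the host vectors of its mapped genes. Deterministic, training-free.
- `frozen_training`: the host graph is extended with the foreign term
  nodes, walks are started from them, and skip-gram updates are applied
  only to the new rows, with the host center vectors serving as the fixed
  context side (the original context matrix is not retained after host
  training, so the host space itself defines the targets). This is the
  closer analog of re-embedding against a pre-trained model; it is a
  design of this package, since several mechanisms are consistent with
  that description.

Nearest-term queries return host *term* nodes only, ascending by euclidean
distance with ties broken by term identifier.

## The synthetic generator

`synthetic_data` emulates the modular structure of curated collections:
`M` disjoint gene pools, each backing a block of terms that sample
`genes_per_term` genes from their pool plus `noise_genes_per_term` from a
global background pool. Module pools are disjoint by construction, so
within-module overlap exceeds between-module overlap analytically, not
just empirically — between-module Jaccard comes only through the shared
background. The default scale (M = 4 modules, 15 terms each, 50-gene
pools, 20 + 3 genes per term, 200-gene background; ~315 genes, 60 terms,
375 nodes) keeps a full 40-epoch embedding under a minute on one CPU while
leaving unambiguous structure. A matching ortholog table gives a chosen
fraction of genes a 1:1 prefixed alias (`MM_<symbol>`), and
duplicate-term generation emits foreign terms whose aliased gene sets
equal chosen host terms' sets — converting them back and asking for the
nearest host term is then a recovery experiment with known truth.

What the generator does *not* emulate: the heavy-tailed term-size
distribution of real collections (10 to >2000 genes), hierarchical
redundancy (GO parent/child terms), hub genes shared by hundreds of
terms, and the ~10^4-term scale with ~10^8 pairs. Passing tests on
planted data therefore show that the pipeline recovers modular structure
it is pointed at, not that real collections are this well separated.

## Numerical choices and degenerate inputs

- Gene symbols are stripped and uppercased before any set operation, so
  human symbols and converted foreign symbols share one namespace.
- Min–max normalization of a constant vector returns all zeros.
- `P(X >= 0)` is returned as exactly 1 without consulting the
  distribution.
- The MST uses Kruskal with the tie-break (weight, term_a, term_b),
  term_a < term_b lexicographically, making the edge list — not just the
  total weight — deterministic under permutation of the input order.
  MSTs are computed on normalized d64 distances by default (raw is a
  flag); normalization is monotone, so the tree differs from the raw one
  only through tie handling.
- Ortholog-table header detection: a first line is treated as a header
  only if neither field recurs as data in its column *and* at least one
  field is a conventional header token (`source`, `target`, `gene`,
  `human`, `mouse`, ...). Recurrence alone cannot decide: in a strict 1:1
  map every symbol is unique, and recurrence-only detection would eat the
  first data line of every such table.
- Empty gene sets, empty collections, k > n for k-means or k ≤ 0 for
  nearest-term queries, non-symmetric or non-finite distance matrices,
  and walk corpora referencing unknown nodes are rejected with errors,
  not repaired.

## Verification

Every closed-form statistic is tested against an independent brute-force
oracle: the hypergeometric tail against exhaustive enumeration of draws
(universes ≤ 12), Silhouette and Davies–Bouldin against direct evaluation
of their defining formulas (random instances, n ≤ 30, agreement to 1e-9),
pairwise distances against a double loop, and the MST against enumeration
of all 125 spanning trees on 5 nodes. Walk behavior is checked against a
shortest-path oracle (the three-case weights, normalization, and the
unreachability of the middle branch on bipartite graphs) and by a
displacement experiment (low q walks travel farther along a path).
Recovery experiments run the default synthetic conditions over five
seeds: mean within-module term distance below between-module distance,
Silhouette at k = 4 above k = 8, a negative Spearman correlation between
normalized distance and Jaccard, and ≥90% nearest-neighbor recovery of
aliased duplicate terms under `neighbor_mean` projection.
`scripts/acceptance.py` recomputes all of these from scratch.

## Limitations

- The skip-gram trainer is single-threaded; at the ~10^4-term scale of a
  full curated database a 2700-point grid search is a cluster job, not a
  laptop one. The implementation targets correctness and reproducibility
  at analysis scale.
- Reliability scores (the 0–5 literature-support grade for a term pair)
  are manual curation; the pair table carries them as an optional
  annotation column and the package never computes them.
- Distance metric (euclidean) and normalization (global min–max) are
  package conventions; cosine and per-run alternatives are exposed where
  they matter.
- The two projection strategies bracket plausible mechanisms for
  embedding a second species against a frozen model; neither is claimed
  to be *the* reference mechanism.
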