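# Methods

## Model and workflow

`bubbletree` summarizes a clustered low-dimensional embedding
`A ∈ R^{n×f}` (n cells, f features such as PC scores) as a rooted
consensus dendrogram whose tips ("bubbles") are cell clusters. The
workflow has four stages — resolution selection, clustering,
hierarchical grouping, visualization — each usable independently. The
package deliberately consumes a *finished* embedding: normalization,
feature selection and the projection itself are upstream concerns, and
linear projections that approximately preserve pairwise distances are
assumed (non-linear 2-D maps distort the long-range distances the tree
is meant to encode).

## Gap statistic

For a clustering function applied at resolution ρ (k for k-means, r for
graph community detection), the within-cluster sum of squares W is
compared to its expectation under a null with no cluster structure:

    Gap(ρ) = (1/B_gap) Σ_b log W*_b − log W,
    se(ρ)  = sd_b(log W*_b) · sqrt(1 + 1/B_gap),
    CI     = Gap ± 1.96 · se.

The `sqrt(1 + 1/B_gap)` factor corrects the standard error for the
simulation error of the null mean. Two null spaces are implemented:

- `original_box`: uniform over each observed feature range;
- `scaled_pca` (default): uniform in the box of the PCA-rotated data,
  rotated back. This respects the data's principal axes and is the
  better-calibrated choice for correlated features.

The same `B_gap` null datasets are reused across the whole resolution
grid (so curve points share simulation noise), and the null data pass
through the *entire* clustering pipeline — for `get_r` this includes SNN
graph construction per null dataset, built once and reused across the
grid.

Selection rules (`select_resolution`): `first_se_max` (smallest ρ with
`Gap(ρ) ≥ Gap(ρ_next) − se(ρ_next)`, the standard one-SE rule),
`global_max`, and `elbow` (largest drop in the discrete slope of Gap
against the induced community count k′, after deduplicating resolutions
that map to the same k′). A curve with no positive second difference has
no elbow; the code warns and falls back to `global_max`. Automated
selection is a convenience — the full curve with CIs is always returned
and should be inspected.

`B_gap` defaults to 20: enough for a stable one-SE decision on clearly
separated data while keeping repeated-clustering cost linear in the
grid size.

## Gini impurity

With L reference labels and π_ij the relative frequency of label j in
cluster i (n_i cells):

    GI_i = Σ_j π_ij (1 − π_ij),        0 ≤ GI_i ≤ 1 − 1/L,
    WGI  = Σ_i GI_i · n_i / n.

WGI inherits the same bounds and equals the size-weighted mean of the
per-cluster impurities by construction; refining any cluster into
label-pure subclusters cannot increase WGI (both properties are tested,
against a direct-formula oracle on randomized label tables). Cells with
missing labels are dropped with a logged count; clusters left empty are
excluded with a warning.

## Clustering

- **SNN graph.** kNN sets of size `n_neighbors` *including the cell
  itself* (default 50, the convention for large single-cell samples);
  edge weight = Jaccard overlap of the two kNN sets; edges below
  `prune_threshold = 1/15` removed. Neighbors are found by chunked
  brute-force distance computation with a stable argsort, so ties are
  broken by cell index and results are bit-reproducible; a warning is
  emitted when ties at the kNN boundary were actually broken.
- **Community detection.** Louvain (igraph multilevel) or Leiden
  (leidenalg, RB-configuration quality) at resolution r, best of
  `n_starts = 20` seeded restarts by quality at that resolution. The
  "Louvain with multilevel refinement" and "smart local moving" variants
  have no native implementation in the installed graph stack; requesting
  them runs plain Louvain and says so loudly (never silently).
- **k-means.** scikit-learn, k-means++ init, `n_starts` restarts, best
  inertia.
- **Pass-through.** `from_assignments` validates an external labelling
  so methods like PhenoGraph or model-based clustering can feed the tree
  stages directly.

Labels are always renamed "0", "1", … by decreasing cluster size (ties
by original label), so bubble 0 is the largest cluster in every figure.

## Bootstrap inter-cluster distances

The exact mean inter-cluster distance requires all n_i·n_j pairwise
distances; over all cells this is O(n²) memory — 7,450 GiB for 10⁶
cells at 8 bytes per entry (`memory_estimate`), which motivates the
estimator. For each iteration b = 1..B and cluster pair (i, j), draw
with replacement n′_i = min(n_i, N_eff) cells from cluster i and n′_j
from j, and record

    D_b^{ij} = (1/n′_i n′_j) Σ_{x∈X, y∈Y} ‖x − y‖,

i.e. the plug-in mean of the n′_i·n′_j inter-cell distances (Euclidean
by default, Manhattan available). The estimator is unbiased for the
exact all-pairs mean; the acceptance suite verifies agreement within 3
standard errors at B = 5000. Sampling is with replacement even when
n_i ≤ N_eff, keeping the estimator's definition uniform; an
`exact_small_clusters` option (off by default) substitutes the exact
mean when n_i·n_j ≤ N_eff². Defaults B = 1000, N_eff = 200 keep the
cost independent of n beyond the subsample cap.

RNG substreams are derived from `(seed, b, i, j)` via `SeedSequence`
spawn keys, so every entry of the ensemble is independent of iteration
order and of any future parallelization, and identical seeds give
bit-identical ensembles.

## Consensus tree and branch support

Average linkage (UPGMA) on the mean matrix `D̂` gives the consensus
tree; the same linkage on each `D_b` gives bootstrap trees H_b, retained
on the tree object. Support of an internal node of the consensus = the
number of H_b containing an internal node with exactly the same
descendant tip set (rooted clade matching, the default); a
`bipartition` mode also accepts the complementary tip set, under which
the two clades meeting at the root necessarily score equally. Supports
range from 0 (no support) to B. Ties in the linkage are resolved by
SciPy's deterministic merge order (verified to merge the lowest-index
pair first on fully tied input). Single, complete and Ward linkage are
accepted for the consensus but average linkage is the default and the
only one used in the documented workflow.

Note that near-tied entries of `D̂` legitimately produce intermediate
supports: with clusters at the corners of a square, which diagonal
merges first is genuinely ambiguous and the support values say so.

## Serialization

Newick: tips are bubble ids, branch lengths are merge-height
differences (so root-to-tip path length equals the root height and the
encoding is ultrametric), internal labels are support counts. Parsing
(via dendropy) reconstructs the linkage by average linkage on the
implied cophenetic matrix — exact for ultrametric input — and recovers
supports by clade matching. The JSON bundle additionally stores `D̂`,
per-bubble counts and the run configuration (seed, B, N_eff, metric,
linkage); its schema is this package's own design.

## Visualization

All panels share the tree's tip order. Bubble radii are linear in the
cell count, anchored so the largest bubble has a fixed maximum radius;
labels read "id: n (pct%)". Categorical tiles normalize either within
bubbles (rows sum to 100%: composition of a bubble) or across bubbles
(columns sum to 100%: where a label is enriched); numeric tiles support
mean/median/sum/pct_nonzero/pct_zero; violins use Scott's bandwidth
(unspecified upstream; bubbles with < 2 values or zero spread are drawn
as points); per-cell strips sort a bubble's cells by attribute value
and stretch them to a common width so rank position is comparable
across bubbles. Tile annotations are rounded to the nearest tenth while
stored values keep full precision; every panel's backing matrix is
exportable as CSV. `compare_bubbletrees` joins two trees over the same
cells through a shared-cell contingency matrix (facing-trees +
heatmap layout — a design choice of this package, as is the whole
figure composition, which favors static matplotlib panels over a
grammar-of-graphics stack).

## Synthetic data

The generators emulate the geometry of a PCA-projected sample:
isotropic Gaussian blobs with chosen means/σ (`make_gaussian_mixture`),
blob means placed by recursive displacement along per-node axes so the
generative tree topology is known exactly (`make_tree_mixture`; at σ=0
inter-cluster distances equal the inter-mean distances and recovery is
deterministic), and marker-like numeric attributes elevated in one
cluster each, with optional zero-inflation (`make_marker_attributes`).
All generators are bit-reproducible under a fixed seed, and fixtures
are always generated programmatically.

What they do **not** emulate: anisotropic or curved cluster shapes,
unequal per-cluster covariance structure, batch effects, count-level
noise (library size, dropout). Passing tests therefore demonstrate
correctness of the algorithms under well-specified geometry, not
robustness to every property of real scRNA-seq data; the `anisotropy`
option exists to probe shape-driven dispersion of inter-bubble
distances qualitatively.

## Numerical choices and degenerate inputs

- All stochastic operations take an explicit integer seed; derived
  seeds stay below 2³¹.
- kNN ties broken by cell index (stable sort); self is always forced
  into its own kNN set, even among exact duplicates.
- k = n (WCSS 0) is rejected in gap grids, since log W is undefined.
- A resolution grid on which every clustering collapses to one cluster
  returns a curve with a warning rather than failing.
- Empty clusters, non-finite distances, id mismatches and duplicate
  ids are hard validation errors with offending items named.

## Problem sizes

The test suite and the acceptance script run on synthetic mixtures of
n = 100–600 cells in 2 features with B up to 5000 (oracle comparison)
or 1000 (workflow runs), and 20-seed repetitions for the recovery
checks — sizes chosen so the full suite completes in a few minutes on
one CPU while leaving the estimators' statistical behaviour clearly
measurable. The algorithms themselves have no small-n assumptions; the
bootstrap path exists precisely to scale the tree stage to millions of
cells.

## Known limitations

- Brute-force kNN is O(n²) time (chunked, O(n·chunk) memory); for very
  large n an approximate-neighbor backend would be the natural
  extension, at the cost of the exact tie-break determinism.
- No HDF5 single-cell container reader; embeddings enter as
  delimited text (or in memory as arrays/AnnData-derived matrices).
- Multifurcations in a generative topology are resolved arbitrarily
  (but deterministically) by the binary consensus tree.
- The LMR and SLM modularity-optimizer variants fall back to plain
  Louvain (loudly); their dedicated implementations are not bundled.
- Intra-bubble dispersion is not estimated: the tree assigns distance
  zero within a bubble.
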