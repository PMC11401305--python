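"""Bootstrap inter-cluster distances and the consensus bubble dendrogram.

Computing all pairwise cell-cell distances for hierarchical grouping of
clusters needs O(n^2) memory — about 7,450 GiB for a million cells at 8
bytes per matrix entry — so inter-cluster distances are instead estimated
by bootstrap: in each of B iterations, up to N_eff cells are drawn with
replacement from each cluster and the mean inter-cell distance between
the drawn subsets is recorded.  The elementwise mean of the B distance
matrices feeds average-linkage clustering to give the consensus tree;
the per-iteration trees yield branch (clade) support counts in [0, B].
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import cdist, pdist, squareform
from scipy.stats import rankdata

from .io_model import ClusterAssignment, Embedding, ValidationError

__all__ = [
    "BootstrapConfig",
    "DistanceEnsemble",
    "BubbleTree",
    "exact_pair_distance",
    "memory_estimate",
    "memory_estimate_gb",
    "bootstrap_distances",
    "build_tree",
    "branch_support",
    "get_bubbletree",
    "rank_pair_distance",
]

_METRICS = {"euclidean": "euclidean", "manhattan": "cityblock"}
_LINKAGES = ("average", "single", "complete", "ward")


@dataclass
class BootstrapConfig:
    """Settings of the bootstrap distance estimator and tree construction.

    Defaults follow common practice for samples of a few thousand to a few
    hundred thousand cells: B=1000 bootstrap iterations, at most N_eff=200
    cells drawn per cluster, Euclidean distances, average linkage.
    """

    B: int = 1000
    N_eff: int = 200
    metric: str = "euclidean"
    linkage: str = "average"
    seed: int = 0
    exact_small_clusters: bool = False

    def __post_init__(self) -> None:
        if self.B < 1:
            raise ValueError("B must be >= 1")
        if self.N_eff < 1:
            raise ValueError("N_eff must be >= 1")
        if self.metric not in _METRICS:
            raise ValueError(f"unknown metric {self.metric!r}")
        if self.linkage not in _LINKAGES:
            raise ValueError(f"unknown linkage {self.linkage!r}")

    def to_dict(self) -> dict:
        return {
            "B": self.B, "N_eff": self.N_eff, "metric": self.metric,
            "linkage": self.linkage, "seed": self.seed,
            "exact_small_clusters": self.exact_small_clusters,
        }


@dataclass
class DistanceEnsemble:
    """B bootstrap k×k distance matrices and their elementwise mean."""

    per_iteration: np.ndarray     # (B, k, k)
    mean: np.ndarray              # (k, k)
    cluster_ids: list[str]
    subsample_sizes: np.ndarray   # n'_i = min(n_i, N_eff)
    cluster_sizes: np.ndarray     # n_i
    config: BootstrapConfig

    @property
    def k(self) -> int:
        return len(self.cluster_ids)

    @property
    def B(self) -> int:
        return self.per_iteration.shape[0]


def exact_pair_distance(X: np.ndarray, Y: np.ndarray,
                        metric: str = "euclidean") -> float:
    """Mean distance over all |X|·|Y| inter-cell pairs (brute force)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if X.size == 0 or Y.size == 0:
        raise ValidationError("empty cluster")
    if X.shape[1] != Y.shape[1]:
        raise ValidationError("feature dimensions differ")
    return float(cdist(X, Y, metric=_METRICS[metric]).mean())


def memory_estimate(n: int, bytes_per_entry: int = 8) -> int:
    """Bytes needed to store a dense n×n cell-cell distance matrix."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return n * n * bytes_per_entry


def memory_estimate_gb(n: int, bytes_per_entry: int = 8) -> int:
    """Same, in binary gigabytes (2^30 bytes), truncated to an integer."""
    return memory_estimate(n, bytes_per_entry) // 2**30


def bootstrap_distances(embedding: Embedding,
                        assignment: ClusterAssignment,
                        config: BootstrapConfig | None = None
                        ) -> DistanceEnsemble:
    """Bootstrap estimate of mean inter-cluster distances.

    For each iteration b and unordered cluster pair (i, j), draws with
    replacement n'_i = min(n_i, N_eff) cells from cluster i and n'_j from
    cluster j and records the mean of the n'_i·n'_j inter-cell distances.
    RNG substreams are derived from (seed, b, i, j), so results do not
    depend on iteration order.  With ``exact_small_clusters`` set, pairs
    with n_i·n_j <= N_eff^2 use the exact all-pairs mean instead.
    """
    config = config or BootstrapConfig()
    if sorted(assignment.cell_ids) != sorted(embedding.cell_ids):
        raise ValidationError("assignment does not cover the embedding cells")
    members = assignment.members()
    ids = assignment.cluster_ids
    k = len(ids)
    if k < 2:
        raise ValidationError("need at least 2 clusters to build a tree")
    mats = []
    for cid in ids:
        if not members[cid]:
            raise ValidationError(f"cluster {cid!r} has no cells")
        mats.append(embedding.matrix[embedding.index_of(members[cid])])
    sizes = np.array([m.shape[0] for m in mats])
    nsub = np.minimum(sizes, config.N_eff)
    metric = _METRICS[config.metric]

    D = np.zeros((config.B, k, k))
    for i in range(k):
        for j in range(i + 1, k):
            exact = (
                config.exact_small_clusters
                and sizes[i] * sizes[j] <= config.N_eff**2
            )
            if exact:
                d = float(cdist(mats[i], mats[j], metric=metric).mean())
                D[:, i, j] = D[:, j, i] = d
                continue
            for b in range(config.B):
                rng = np.random.default_rng(
                    np.random.SeedSequence(config.seed, spawn_key=(b, i, j))
                )
                xi = rng.integers(0, sizes[i], nsub[i])
                yj = rng.integers(0, sizes[j], nsub[j])
                d = float(cdist(mats[i][xi], mats[j][yj], metric=metric).mean())
                D[b, i, j] = D[b, j, i] = d
    return DistanceEnsemble(
        per_iteration=D, mean=D.mean(axis=0), cluster_ids=list(ids),
        subsample_sizes=nsub, cluster_sizes=sizes, config=config,
    )


# -- the tree ---------------------------------------------------------------

@dataclass
class BubbleTree:
    """Rooted consensus dendrogram whose tips are bubbles (cell clusters).

    ``linkage`` is a SciPy linkage matrix over the tips in ``tip_ids``
    order; merge heights carry the units of the embedding metric.
    ``support[m]`` counts how many bootstrap trees contain the clade
    created by merge m (0..B).
    """

    tip_ids: list[str]
    linkage: np.ndarray
    counts: np.ndarray | None = None
    support: np.ndarray | None = None
    b_iterations: int | None = None
    mean_distance: np.ndarray | None = None
    bootstrap_linkages: np.ndarray | None = None
    assignment: ClusterAssignment | None = None
    config: dict | None = None

    def __post_init__(self) -> None:
        self.linkage = np.asarray(self.linkage, dtype=float)
        if self.counts is None:
            self.counts = np.ones(len(self.tip_ids), dtype=int)
        self.counts = np.asarray(self.counts, dtype=int)

    @property
    def k(self) -> int:
        return len(self.tip_ids)

    @property
    def n_total(self) -> int:
        return int(self.counts.sum())

    def heights(self) -> np.ndarray:
        return self.linkage[:, 2].copy()

    def clades(self) -> list[frozenset[str]]:
        """Descendant tip-id set of each internal node, in merge order."""
        return _linkage_clades(self.linkage, self.tip_ids)

    def tip_order(self) -> list[str]:
        """Tip ids in dendrogram leaf order (top-to-bottom when drawn)."""
        order = hierarchy.leaves_list(self.linkage)
        return [self.tip_ids[i] for i in order]

    def cophenetic(self) -> pd.DataFrame:
        d = squareform(hierarchy.cophenet(self.linkage))
        return pd.DataFrame(d, index=self.tip_ids, columns=self.tip_ids)

    # -- serialization ------------------------------------------------------

    def to_newick(self) -> str:
        """Newick with tips = bubble ids, branch lengths = merge-height
        differences, internal labels = support counts."""
        k = self.k
        Z = self.linkage

        def height(node: int) -> float:
            return 0.0 if node < k else Z[node - k, 2]

        def render(node: int, parent_h: float) -> str:
            bl = float(parent_h - height(node))
            if node < k:
                return f"{_quote(self.tip_ids[node])}:{bl!r}"
            m = node - k
            left = render(int(Z[m, 0]), Z[m, 2])
            right = render(int(Z[m, 1]), Z[m, 2])
            label = "" if self.support is None else str(int(self.support[m]))
            suffix = f":{bl!r}" if node != 2 * k - 2 else ""
            return f"({left},{right}){label}{suffix}"

        root = 2 * k - 2
        return render(root, height(root)) + ";"

    @classmethod
    def from_newick(cls, text: str) -> "BubbleTree":
        """Rebuild a tree from :meth:`to_newick` output.

        Node heights are recovered from root-to-tip path lengths (the
        encoding is ultrametric), the linkage by average linkage on the
        implied cophenetic matrix, and supports by clade matching.
        """
        import dendropy

        dtree = dendropy.Tree.get(
            data=text, schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
        leaves = [lf for lf in dtree.leaf_node_iter()]
        names = [lf.taxon.label for lf in leaves]
        depth = {}
        for nd in dtree.preorder_node_iter():
            depth[nd] = (0.0 if nd.parent_node is None
                         else depth[nd.parent_node]
                         + (nd.edge.length or 0.0))
        root_h = max(depth[lf] for lf in leaves)
        k = len(names)
        coph = np.zeros((k, k))
        pdm = dtree.phylogenetic_distance_matrix()
        node_height = {nd: root_h - depth[nd]
                       for nd in dtree.preorder_node_iter()}
        for i in range(k):
            for j in range(i + 1, k):
                mrca = pdm.mrca(leaves[i].taxon, leaves[j].taxon)
                coph[i, j] = coph[j, i] = node_height[mrca]
        Z = hierarchy.linkage(squareform(coph), method="average")
        tree = cls(tip_ids=names, linkage=Z)
        # recover support labels, if present, by clade matching
        clade_support = {}
        for nd in dtree.preorder_internal_node_iter():
            if nd.label is not None and nd.label != "":
                tipset = frozenset(
                    lf.taxon.label for lf in nd.leaf_iter()
                )
                clade_support[tipset] = int(float(nd.label))
        if clade_support:
            sup = np.zeros(k - 1, dtype=int)
            for m, clade in enumerate(tree.clades()):
                sup[m] = clade_support.get(clade, 0)
            tree.support = sup
        return tree


def _quote(label: str) -> str:
    if any(ch in label for ch in " (),:;'[]"):
        return "'" + label.replace("'", "''") + "'"
    return label


def _linkage_clades(Z: np.ndarray, tip_ids: Sequence[str]
                    ) -> list[frozenset[str]]:
    k = len(tip_ids)
    sets: list[frozenset[str]] = [frozenset([t]) for t in tip_ids]
    out = []
    for a, b in Z[:, :2].astype(int):
        merged = sets[a] | sets[b]
        sets.append(merged)
        out.append(merged)
    return out


def build_tree(ensemble: DistanceEnsemble,
               linkage: str | None = None,
               counts: Mapping[str, int] | None = None) -> BubbleTree:
    """Consensus dendrogram from the mean bootstrap distance matrix.

    The per-iteration trees H_b are built alongside (same linkage) and
    retained on the returned tree for support counting.  Average-linkage
    ties are resolved deterministically by SciPy's merge order.
    """
    method = linkage or ensemble.config.linkage
    if not np.isfinite(ensemble.mean).all():
        raise ValidationError("non-finite distances in ensemble mean")
    if ensemble.k < 2:
        raise ValidationError("need at least 2 clusters")
    Z = hierarchy.linkage(squareform(ensemble.mean, checks=False),
                          method=method)
    boot = np.empty((ensemble.B, ensemble.k - 1, 4))
    for b in range(ensemble.B):
        boot[b] = hierarchy.linkage(
            squareform(ensemble.per_iteration[b], checks=False),
            method=method,
        )
    if counts is None:
        tip_counts = ensemble.cluster_sizes
    else:
        tip_counts = np.array([counts[t] for t in ensemble.cluster_ids])
    return BubbleTree(
        tip_ids=list(ensemble.cluster_ids), linkage=Z, counts=tip_counts,
        b_iterations=ensemble.B, mean_distance=ensemble.mean.copy(),
        bootstrap_linkages=boot,
        config=ensemble.config.to_dict() | {"linkage": method},
    )


def branch_support(consensus: BubbleTree,
                   bootstrap_trees: Sequence[BubbleTree] | None = None,
                   mode: str = "clade") -> BubbleTree:
    """Count, for each internal node of the consensus tree, how many
    bootstrap trees contain it; fills ``consensus.support`` in place.

    ``mode="clade"`` matches rooted descendant-tip sets; ``"bipartition"``
    also accepts the complementary tip set (unrooted comparison).
    """
    if mode not in ("clade", "bipartition"):
        raise ValueError(f"unknown mode {mode!r}")
    tips = frozenset(consensus.tip_ids)
    if bootstrap_trees is not None:
        boot_clades = []
        for t in bootstrap_trees:
            if frozenset(t.tip_ids) != tips:
                raise ValidationError("bootstrap tree tip set mismatch")
            boot_clades.append(set(t.clades()))
    elif consensus.bootstrap_linkages is not None:
        boot_clades = [
            set(_linkage_clades(Zb, consensus.tip_ids))
            for Zb in consensus.bootstrap_linkages
        ]
    else:
        raise ValidationError("no bootstrap trees available")

    target = consensus.clades()
    support = np.zeros(len(target), dtype=int)
    for m, clade in enumerate(target):
        comp = tips - clade
        for cl in boot_clades:
            if clade in cl or (mode == "bipartition" and comp in cl):
                support[m] += 1
    consensus.support = support
    consensus.b_iterations = len(boot_clades)
    return consensus


def get_bubbletree(embedding: Embedding,
                   assignment: ClusterAssignment,
                   config: BootstrapConfig | None = None) -> BubbleTree:
    """Full tree stage: bootstrap distances, consensus tree, supports."""
    config = config or BootstrapConfig()
    ensemble = bootstrap_distances(embedding, assignment, config)
    tree = build_tree(ensemble)
    branch_support(tree)
    tree.assignment = assignment
    return tree


def rank_pair_distance(profiles, pair: tuple[str, str],
                       metric: str = "euclidean") -> dict:
    """Rank the distance of one named pair among all pairwise distances.

    ``profiles`` maps m names to equal-length numeric vectors (dict or
    DataFrame with profiles as columns).  Returns the ascending rank of
    the requested pair (ties share the minimum rank), the total number of
    unordered pairs m(m-1)/2, and the distance itself.
    """
    if isinstance(profiles, pd.DataFrame):
        names = list(profiles.columns)
        X = profiles.to_numpy(dtype=float).T
    else:
        names = list(profiles)
        lengths = {len(np.asarray(profiles[n]).ravel()) for n in names}
        if len(lengths) > 1:
            raise ValidationError("profile vectors have unequal lengths")
        X = np.array([np.asarray(profiles[n], dtype=float).ravel()
                      for n in names])
    if len(names) < 2:
        raise ValidationError("need at least 2 profiles")
    for p in pair:
        if p not in names:
            raise ValidationError(f"unknown profile {p!r}")
    d = pdist(X, metric=_METRICS[metric])
    ranks = rankdata(d, method="min")
    i, j = sorted((names.index(pair[0]), names.index(pair[1])))
    m = len(names)
    flat = m * i - (i * (i + 1)) // 2 + (j - i - 1)
    return {
        "rank": int(ranks[flat]),
        "n_pairs": m * (m - 1) // 2,
        "distance": float(d[flat]),
    }
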