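"""Cluster an embedding: SNN-graph community detection, k-means, or
externally supplied assignments.

Graph clustering follows the standard single-cell recipe: a shared
nearest neighbor (SNN) graph whose edge weights are the Jaccard overlap
of the two cells' k-nearest-neighbor sets (each set including the cell
itself), pruned at a small threshold, then modularity-based community
detection at a resolution r.  Labels are always renamed "0", "1", ... in
decreasing cluster size, so label "0" is the largest cluster.
"""

from __future__ import annotations

import random
import warnings
from dataclasses import dataclass

import igraph as ig
import leidenalg
import numpy as np
from scipy.spatial.distance import cdist
from sklearn.cluster import KMeans

from .io_model import ClusterAssignment, Embedding, ValidationError

__all__ = [
    "SNNParams",
    "SNNGraph",
    "CommunityParams",
    "build_snn_graph",
    "cluster_graph",
    "cluster_kmeans",
    "from_assignments",
]

_METRICS = {"euclidean": "euclidean", "manhattan": "cityblock"}


@dataclass
class SNNParams:
    """Shared-nearest-neighbor graph construction parameters.

    ``n_neighbors`` counts the cell itself; the conventional default for
    large samples is 50.  Edges with Jaccard weight below
    ``prune_threshold`` (default 1/15, the usual SNN pruning cutoff) are
    removed.
    """

    n_neighbors: int = 50
    prune_threshold: float = 1.0 / 15.0
    metric: str = "euclidean"

    def __post_init__(self) -> None:
        if self.n_neighbors < 1:
            raise ValueError("n_neighbors must be >= 1")
        if not 0.0 <= self.prune_threshold <= 1.0:
            raise ValueError("prune_threshold must be in [0, 1]")
        if self.metric not in _METRICS:
            raise ValueError(f"unknown metric {self.metric!r}")


@dataclass
class SNNGraph:
    """Undirected weighted graph over cells; weights in (0, 1]."""

    n_vertices: int
    edges: np.ndarray        # (m, 2) int vertex pairs, i < j
    weights: np.ndarray      # (m,) float

    def to_igraph(self) -> ig.Graph:
        g = ig.Graph(
            n=self.n_vertices, edges=[tuple(e) for e in self.edges],
            directed=False,
        )
        g.es["weight"] = list(self.weights)
        return g


@dataclass
class CommunityParams:
    """Community-detection settings: algorithm, resolution r, restarts."""

    algorithm: str = "louvain"
    resolution: float = 1.0
    n_starts: int = 20
    max_iter: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.algorithm not in ("louvain", "louvain_mlr", "slm", "leiden"):
            raise ValueError(f"unsupported algorithm {self.algorithm!r}")
        if self.resolution <= 0:
            raise ValueError("resolution must be > 0")
        if self.n_starts < 1:
            raise ValueError("n_starts must be >= 1")


def _knn_sets(X: np.ndarray, n_neighbors: int, metric: str,
              chunk: int = 2048) -> np.ndarray:
    """Indices of the n_neighbors nearest cells (self included, ties broken
    by cell index).  Brute force with a stable sort for determinism."""
    n = X.shape[0]
    out = np.empty((n, n_neighbors), dtype=np.int64)
    tied = False
    for start in range(0, n, chunk):
        stop = min(start + chunk, n)
        d = cdist(X[start:stop], X, metric=_METRICS[metric])
        # force self to the front even among exact duplicates
        d[np.arange(stop - start), np.arange(start, stop)] = -1.0
        order = np.argsort(d, axis=1, kind="stable")
        if not tied and n > n_neighbors:
            kth = np.take_along_axis(d, order[:, [n_neighbors - 1]], axis=1)
            nxt = np.take_along_axis(d, order[:, [n_neighbors]], axis=1)
            if np.any(kth == nxt):
                tied = True
        out[start:stop] = order[:, :n_neighbors]
    if tied:
        warnings.warn(
            "ties at the kNN boundary broken by cell index", stacklevel=2
        )
    return out


def build_snn_graph(embedding: Embedding,
                    params: SNNParams | None = None) -> SNNGraph:
    """Build the SNN graph: kNN sets, Jaccard edge weights, pruning.

    Two cells are connected iff their kNN sets overlap and the Jaccard
    index |A∩B| / |A∪B| is at least ``prune_threshold``.
    """
    params = params or SNNParams()
    n = embedding.n
    if n <= params.n_neighbors:
        raise ValidationError(
            f"n_neighbors={params.n_neighbors} requires more than "
            f"{params.n_neighbors} cells, got {n}"
        )
    knn = _knn_sets(embedding.matrix, params.n_neighbors, params.metric)

    from scipy import sparse

    k = params.n_neighbors
    indptr = np.arange(0, n * k + 1, k)
    S = sparse.csr_matrix(
        (np.ones(n * k, dtype=np.int32), knn.ravel(), indptr), shape=(n, n)
    )
    inter = (S @ S.T).tocoo()
    mask = inter.row < inter.col
    i, j, shared = inter.row[mask], inter.col[mask], inter.data[mask]
    jacc = shared / (2 * k - shared)
    keep = jacc >= params.prune_threshold
    order = np.lexsort((j[keep], i[keep]))
    edges = np.column_stack([i[keep][order], j[keep][order]])
    return SNNGraph(n_vertices=n, edges=edges, weights=jacc[keep][order])


def _relabel_by_size(membership: np.ndarray) -> list[str]:
    """Rename integer communities "0","1",... by decreasing size
    (ties by original community index)."""
    comms, counts = np.unique(membership, return_counts=True)
    order = np.lexsort((comms, -counts))
    rename = {int(comms[o]): str(rank) for rank, o in enumerate(order)}
    return [rename[int(m)] for m in membership]


def cluster_graph(graph: SNNGraph | ig.Graph,
                  params: CommunityParams,
                  cell_ids: list[str] | None = None,
                  return_details: bool = False):
    """Community detection on an SNN graph at resolution r.

    Runs ``n_starts`` seeded restarts and keeps the partition with the
    best quality at that resolution (modularity for Louvain, the RB
    configuration quality for Leiden).  The ``louvain_mlr`` and ``slm``
    modularity-optimizer variants have no native implementation here;
    they fall back to the plain Louvain optimizer with an explicit
    warning naming the algorithm that actually ran.
    """
    g = graph.to_igraph() if isinstance(graph, SNNGraph) else graph
    if g.vcount() == 0:
        raise ValidationError("empty graph")
    weights = g.es["weight"] if "weight" in g.es.attributes() else None

    algorithm = params.algorithm
    if algorithm in ("louvain_mlr", "slm"):
        warnings.warn(
            f"algorithm {algorithm!r} has no native implementation; "
            "running the plain Louvain (multilevel) optimizer instead",
            stacklevel=2,
        )
        algorithm = "louvain"

    ss = np.random.SeedSequence(params.seed)
    start_seeds = [int(s) for s in ss.generate_state(params.n_starts) >> 1]
    best = None
    qualities = []
    for s in start_seeds:
        if algorithm == "louvain":
            state = random.getstate()
            try:
                random.seed(s)
                memb = np.asarray(
                    g.community_multilevel(
                        weights=weights, resolution=params.resolution
                    ).membership
                )
            finally:
                random.setstate(state)
            q = g.modularity(
                memb, weights=weights, resolution=params.resolution
            )
        else:  # leiden
            part = leidenalg.find_partition(
                g, leidenalg.RBConfigurationVertexPartition,
                weights=weights, resolution_parameter=params.resolution,
                n_iterations=params.max_iter, seed=s,
            )
            memb = np.asarray(part.membership)
            q = part.quality()
        qualities.append(q)
        if best is None or q > best[0]:
            best = (q, memb)

    labels = _relabel_by_size(best[1])
    ids = cell_ids if cell_ids is not None else [
        f"v{i}" for i in range(g.vcount())
    ]
    assignment = ClusterAssignment(cell_ids=list(ids), labels=labels)
    if return_details:
        return assignment, {
            "qualities": qualities, "best_quality": best[0],
            "algorithm_run": algorithm,
        }
    return assignment


def cluster_embedding_graph(embedding: Embedding,
                            resolution: float,
                            snn_params: SNNParams | None = None,
                            community_params: CommunityParams | None = None,
                            graph: SNNGraph | None = None) -> ClusterAssignment:
    """SNN graph + community detection in one call (graph reusable)."""
    if graph is None:
        graph = build_snn_graph(embedding, snn_params)
    cp = community_params or CommunityParams()
    cp = CommunityParams(
        algorithm=cp.algorithm, resolution=resolution,
        n_starts=cp.n_starts, max_iter=cp.max_iter, seed=cp.seed,
    )
    return cluster_graph(graph, cp, cell_ids=embedding.cell_ids)


def cluster_kmeans(embedding: Embedding, k: int,
                   n_starts: int = 20, seed: int = 0) -> ClusterAssignment:
    """k-means with k-means++ initialization and ``n_starts`` restarts;
    the best-inertia solution is kept and labels renamed by size."""
    if not 1 <= k <= embedding.n:
        raise ValidationError(
            f"k={k} out of range for n={embedding.n} cells"
        )
    km = KMeans(
        n_clusters=k, n_init=n_starts, init="k-means++",
        random_state=int(np.random.SeedSequence(seed).generate_state(1)[0] >> 1),
    ).fit(embedding.matrix)
    return ClusterAssignment(
        cell_ids=list(embedding.cell_ids),
        labels=_relabel_by_size(km.labels_),
    )


def from_assignments(embedding: Embedding,
                     labels) -> ClusterAssignment:
    """Adopt an externally produced per-cell labelling (pass-through mode).

    ``labels`` may be a sequence aligned to the embedding rows or a
    mapping/Series keyed by cell id.  Downstream stages treat the result
    exactly like an internally clustered partition.
    """
    import pandas as pd

    if isinstance(labels, pd.Series):
        labels = labels.to_dict()
    if isinstance(labels, dict):
        missing = [c for c in embedding.cell_ids if c not in labels]
        if missing:
            raise ValidationError(
                f"labels missing for cells: {missing[:10]}"
            )
        extra = [c for c in labels if c not in set(embedding.cell_ids)]
        if extra:
            raise ValidationError(f"labels for unknown cells: {extra[:10]}")
        lab = [labels[c] for c in embedding.cell_ids]
    else:
        lab = list(labels)
        if len(lab) != embedding.n:
            raise ValidationError(
                f"{len(lab)} labels for {embedding.n} cells"
            )
    return ClusterAssignment(
        cell_ids=list(embedding.cell_ids), labels=[str(x) for x in lab]
    )
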