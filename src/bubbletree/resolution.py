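"""Clustering-resolution selection: gap statistic and Gini impurity.

The gap statistic compares the log within-cluster sum of squares (WCSS)
of a clustering of the data to its expectation under a null reference
(uniform over the data's bounding box, optionally in PCA-rotated
coordinates).  A clear maximum or an "elbow" of the gap curve over the
resolution grid indicates an appropriate number of clusters.

Where per-cell reference labels exist (e.g. predicted subtypes), cluster
purity offers a complementary criterion: the Gini impurity of cluster i,

    GI_i = sum_j pi_ij (1 - pi_ij),

with pi_ij the relative frequency of label j in cluster i, is near 0 for
homogeneous clusters and approaches 1 - 1/L for uniformly mixed ones;
the weighted Gini impurity WGI = sum_i GI_i n_i / n aggregates over a
partition and drops once the resolution suffices to separate the labels.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .clustering import (
    CommunityParams,
    SNNParams,
    build_snn_graph,
    cluster_graph,
    cluster_kmeans,
)
from .io_model import ClusterAssignment, Embedding, ValidationError

__all__ = [
    "GapCurve",
    "GiniResult",
    "wcss",
    "gap_statistic",
    "get_k",
    "get_r",
    "select_resolution",
    "get_gini",
    "wgi_curve",
]

logger = logging.getLogger(__name__)

# 95% two-sided normal quantile for the gap confidence interval
_Z95 = 1.959963984540054


def wcss(embedding: Embedding, assignment: ClusterAssignment) -> float:
    """Within-cluster sum of squares: total squared Euclidean distance of
    cells to their cluster centroid."""
    if sorted(assignment.cell_ids) != sorted(embedding.cell_ids):
        raise ValidationError("assignment does not cover the embedding cells")
    if assignment.k < 1:
        raise ValidationError("no cluster labels")
    total = 0.0
    for cells in assignment.members().values():
        X = embedding.matrix[embedding.index_of(cells)]
        total += float(((X - X.mean(axis=0)) ** 2).sum())
    return total


@dataclass
class GapEntry:
    resolution: float
    k_prime: int
    gap_mean: float
    gap_se: float
    ci_low: float
    ci_high: float
    log_wcss: float


@dataclass
class GapCurve:
    """Gap statistic per resolution, with 95% confidence intervals."""

    entries: list[GapEntry]
    B_gap: int
    kind: str = "k"  # "k" (k-means grid) or "r" (graph resolution grid)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([e.__dict__ for e in self.entries])

    def __len__(self) -> int:
        return len(self.entries)


def _null_reference(matrix: np.ndarray, rng: np.random.Generator,
                    null_space: str) -> np.ndarray:
    """One null dataset: uniform over the feature box, either in the
    original axes or in the PCA-rotated frame (rotated back afterwards)."""
    n, f = matrix.shape
    if null_space == "original_box":
        lo, hi = matrix.min(axis=0), matrix.max(axis=0)
        return rng.uniform(lo, hi, size=(n, f))
    if null_space == "scaled_pca":
        center = matrix.mean(axis=0)
        Xc = matrix - center
        _, _, Vt = np.linalg.svd(Xc, full_matrices=False)
        rotated = Xc @ Vt.T
        lo, hi = rotated.min(axis=0), rotated.max(axis=0)
        draw = rng.uniform(lo, hi, size=(n, f))
        return draw @ Vt + center
    raise ValueError(f"unknown null_space {null_space!r}")


def gap_statistic(embedding: Embedding,
                  cluster_fn: Callable[[Embedding, float, int],
                                       ClusterAssignment],
                  resolutions: Sequence[float],
                  B_gap: int = 20,
                  null_space: str = "scaled_pca",
                  seed: int = 0,
                  kind: str = "k") -> GapCurve:
    """Gap curve over a resolution grid.

    ``cluster_fn(embedding, resolution, seed)`` must return a
    ClusterAssignment; it is applied identically to the observed data and
    to each of ``B_gap`` null reference datasets.  For each resolution:

        gap    = mean_b log W*_b - log W
        gap_se = sd_b(log W*_b) * sqrt(1 + 1/B_gap)
        CI     = gap ± 1.96 * gap_se

    where W is the WCSS of the observed clustering and W*_b of the b-th
    null clustering at the same resolution.
    """
    if B_gap < 2:
        raise ValidationError("B_gap must be >= 2")
    if len(resolutions) == 0:
        raise ValidationError("empty resolution grid")
    ss = np.random.SeedSequence(seed)
    null_rngs = [np.random.default_rng(s) for s in ss.spawn(B_gap)]
    nulls = [
        Embedding(
            cell_ids=list(embedding.cell_ids),
            matrix=_null_reference(embedding.matrix, rng, null_space),
            feature_names=list(embedding.feature_names),
        )
        for rng in null_rngs
    ]
    cluster_seeds = (ss.generate_state(1 + B_gap, dtype=np.uint32) >> 1)

    entries = []
    any_structure = False
    for res in resolutions:
        a = cluster_fn(embedding, res, int(cluster_seeds[0]))
        w = wcss(embedding, a)
        if w <= 0:
            raise ValidationError(
                f"WCSS is 0 at resolution {res} (every cell its own "
                "cluster); shrink the grid"
            )
        log_w = float(np.log(w))
        log_wstar = np.empty(B_gap)
        for b, null_emb in enumerate(nulls):
            a_null = cluster_fn(null_emb, res, int(cluster_seeds[1 + b]))
            log_wstar[b] = np.log(wcss(null_emb, a_null))
        gap = float(log_wstar.mean() - log_w)
        se = float(log_wstar.std(ddof=1) * np.sqrt(1.0 + 1.0 / B_gap))
        entries.append(GapEntry(
            resolution=float(res), k_prime=a.k, gap_mean=gap, gap_se=se,
            ci_low=gap - _Z95 * se, ci_high=gap + _Z95 * se,
            log_wcss=log_w,
        ))
        any_structure = any_structure or a.k > 1
    if not any_structure:
        warnings.warn(
            "every resolution produced a single cluster; the gap curve "
            "carries no resolution signal", stacklevel=2,
        )
    return GapCurve(entries=entries, B_gap=B_gap, kind=kind)


def get_k(embedding: Embedding,
          k_grid: Sequence[int],
          B_gap: int = 20,
          seed: int = 0,
          n_starts: int = 20,
          null_space: str = "scaled_pca") -> GapCurve:
    """Gap curve for k-means over an integer grid of k."""
    k_grid = [int(k) for k in k_grid]
    bad = [k for k in k_grid if not 1 <= k < embedding.n]
    if bad:
        raise ValidationError(
            f"k values out of range 1 <= k < n={embedding.n}: {bad}"
        )

    def fn(emb: Embedding, res: float, s: int) -> ClusterAssignment:
        return cluster_kmeans(emb, int(res), n_starts=n_starts, seed=s)

    return gap_statistic(embedding, fn, k_grid, B_gap=B_gap,
                         null_space=null_space, seed=seed, kind="k")


def get_r(embedding: Embedding,
          r_grid: Sequence[float],
          snn_params: SNNParams | None = None,
          community_params: CommunityParams | None = None,
          B_gap: int = 20,
          seed: int = 0,
          null_space: str = "scaled_pca") -> GapCurve:
    """Gap curve for SNN-graph community detection over a grid of r.

    The null datasets pass through the same graph construction and
    community detection as the observed data; each dataset's SNN graph is
    built once and reused across the grid.
    """
    if any(r <= 0 for r in r_grid):
        raise ValidationError("r grid must be positive")
    snn_params = snn_params or SNNParams()
    cp = community_params or CommunityParams()
    if embedding.n <= snn_params.n_neighbors:
        raise ValidationError(
            f"graph construction needs n > n_neighbors="
            f"{snn_params.n_neighbors}"
        )
    graphs: dict[int, object] = {}

    def fn(emb: Embedding, res: float, s: int) -> ClusterAssignment:
        key = id(emb)
        if key not in graphs:
            graphs[key] = build_snn_graph(emb, snn_params)
        params = CommunityParams(
            algorithm=cp.algorithm, resolution=float(res),
            n_starts=cp.n_starts, max_iter=cp.max_iter, seed=s,
        )
        return cluster_graph(graphs[key], params, cell_ids=emb.cell_ids)

    return gap_statistic(embedding, fn, list(r_grid), B_gap=B_gap,
                         null_space=null_space, seed=seed, kind="r")


def select_resolution(curve: GapCurve, rule: str = "first_se_max") -> float:
    """Pick a resolution from a gap curve.

    - ``first_se_max``: smallest resolution whose gap >= next gap - next SE;
    - ``global_max``:   argmax of the mean gap;
    - ``elbow``:        resolution with the largest drop in discrete slope
      (second difference) of gap against k'.

    A curve with no discernible elbow falls back to ``global_max`` with a
    warning.  The full curve should always be inspected alongside the
    automated pick.
    """
    if len(curve) == 0:
        raise ValidationError("empty gap curve")
    entries = curve.entries
    gaps = np.array([e.gap_mean for e in entries])
    if rule == "global_max":
        return entries[int(np.argmax(gaps))].resolution
    if rule == "first_se_max":
        for i in range(len(entries) - 1):
            if gaps[i] >= gaps[i + 1] - entries[i + 1].gap_se:
                return entries[i].resolution
        return entries[-1].resolution
    if rule == "elbow":
        # deduplicate by k': keep the smallest resolution per k'
        seen: dict[int, GapEntry] = {}
        for e in entries:
            seen.setdefault(e.k_prime, e)
        uniq = sorted(seen.values(), key=lambda e: e.k_prime)
        if len(uniq) < 3:
            warnings.warn("too few distinct k' for elbow detection; "
                          "falling back to global_max", stacklevel=2)
            return select_resolution(curve, "global_max")
        kp = np.array([e.k_prime for e in uniq], dtype=float)
        g = np.array([e.gap_mean for e in uniq])
        slopes = np.diff(g) / np.diff(kp)
        drop = slopes[:-1] - slopes[1:]  # at uniq[1..-2]
        if drop.max() <= 1e-12:
            warnings.warn("gap curve has no elbow; falling back to "
                          "global_max", stacklevel=2)
            return select_resolution(curve, "global_max")
        return uniq[1 + int(np.argmax(drop))].resolution
    raise ValueError(f"unknown rule {rule!r}")


@dataclass
class GiniResult:
    """Per-cluster Gini impurities and their size-weighted mean."""

    per_cluster: pd.DataFrame   # index cluster id; columns n_i, GI
    label_freqs: pd.DataFrame   # pi_ij, rows = clusters, cols = labels
    WGI: float
    L: int
    n_dropped: int = 0


def get_gini(labels: pd.Series,
             assignment: ClusterAssignment) -> GiniResult:
    """Gini impurity of each cluster's label composition, and the WGI.

    ``labels`` is a categorical Series indexed by cell id.  Cells with a
    missing label are dropped (count logged); clusters left empty after
    dropping are excluded with a warning.
    """
    lab = labels.reindex(assignment.cell_ids)
    missing = lab.isna()
    n_dropped = int(missing.sum())
    if n_dropped:
        logger.info("get_gini: dropped %d cells with missing labels",
                    n_dropped)
    clus = assignment.as_series()[~missing.to_numpy()]
    lab = lab[~missing.to_numpy()].astype(str)
    if lab.empty:
        raise ValidationError("no labelled cells")
    empty = [c for c in assignment.cluster_ids if c not in set(clus)]
    if empty:
        warnings.warn(f"clusters without labelled cells excluded: {empty}",
                      stacklevel=2)
    ct = pd.crosstab(clus, lab)
    ct = ct.loc[[c for c in assignment.cluster_ids if c in ct.index]]
    n_i = ct.sum(axis=1)
    pi = ct.div(n_i, axis=0)
    gi = (pi * (1.0 - pi)).sum(axis=1)
    n = float(n_i.sum())
    wgi = float((gi * n_i / n).sum())
    per_cluster = pd.DataFrame({"n_i": n_i, "GI": gi})
    per_cluster.index.name = "cluster"
    return GiniResult(
        per_cluster=per_cluster, label_freqs=pi, WGI=wgi,
        L=ct.shape[1], n_dropped=n_dropped,
    )


def wgi_curve(labels: pd.Series,
              assignments: Sequence[tuple[float, ClusterAssignment]]
              ) -> pd.DataFrame:
    """WGI per resolution, for plotting next to the gap curve.

    ``assignments`` pairs each resolution value with its partition.
    """
    rows = []
    for res, a in assignments:
        g = get_gini(labels, a)
        rows.append({"resolution": res, "k_prime": a.k, "WGI": g.WGI})
    return pd.DataFrame(rows)
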