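"""Seeded generators for embeddings with known cluster ground truth.

These emulate the geometry of a PCA-projected scRNA-seq sample — compact,
roughly isotropic clusters in a low-dimensional feature space — so every
downstream stage (resolution selection, clustering, tree building,
annotation panels) can be exercised against a known answer.  They do not
attempt realistic count-level simulation (library size, dropout beyond a
simple zero-inflation option).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .io_model import AttributeTable, Embedding

__all__ = [
    "MixtureSpec",
    "make_gaussian_mixture",
    "make_tree_mixture",
    "make_marker_attributes",
    "clade_sets",
]

Topology = tuple | str  # nested tuples of cluster names, e.g. (("A","B"),"C")


@dataclass
class MixtureSpec:
    """Parameters of a Gaussian mixture in f dimensions.

    ``means`` has one row per cluster; ``sd`` is the isotropic standard
    deviation (scalar, or one value per cluster).  ``anisotropy`` optionally
    stretches each cluster along its first axis by the given factor, to
    emulate non-spherical clusters.
    """

    sizes: Sequence[int]
    means: np.ndarray
    sd: float | Sequence[float] = 1.0
    seed: int = 0
    names: Sequence[str] | None = None
    anisotropy: float = 1.0
    tree: Topology | None = None

    def __post_init__(self) -> None:
        self.means = np.atleast_2d(np.asarray(self.means, dtype=float))
        if len(self.sizes) != self.means.shape[0]:
            raise ValueError("one size per cluster required")
        if any(s < 1 for s in self.sizes):
            raise ValueError("cluster sizes must be >= 1")
        sds = np.broadcast_to(
            np.asarray(self.sd, dtype=float), (self.k,)
        ).copy()
        if (sds < 0).any():
            raise ValueError("sd must be >= 0")
        self.sd = sds
        if self.names is None:
            self.names = [str(i) for i in range(self.k)]
        if not np.isfinite(self.means).all():
            raise ValueError("means must be finite")

    @property
    def k(self) -> int:
        return self.means.shape[0]

    @property
    def f(self) -> int:
        return self.means.shape[1]


def make_gaussian_mixture(spec: MixtureSpec) -> tuple[Embedding, AttributeTable]:
    """Sample isotropic Gaussian blobs with labels attached as a
    categorical attribute column ``"label"``.

    Bit-reproducible for a fixed ``spec.seed``.
    """
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    rows, ids, labels = [], [], []
    for i, (name, size) in enumerate(zip(spec.names, spec.sizes)):
        x = rng.standard_normal((size, spec.f)) * spec.sd[i]
        if spec.anisotropy != 1.0:
            x[:, 0] *= spec.anisotropy
        rows.append(x + spec.means[i])
        start = len(ids)
        ids.extend(f"c{start + j}" for j in range(size))
        labels.extend([name] * size)
    emb = Embedding(cell_ids=ids, matrix=np.vstack(rows))
    attrs = AttributeTable(
        data=pd.DataFrame(
            {"label": labels}, index=pd.Index(ids, name="cell_id")
        ),
        types={"label": "categorical"},
    )
    return emb, attrs


def _leaves(topology: Topology) -> list[str]:
    if isinstance(topology, str):
        return [topology]
    out: list[str] = []
    for child in topology:
        out.extend(_leaves(child))
    return out


def clade_sets(topology: Topology) -> set[frozenset[str]]:
    """Non-trivial clades (descendant leaf sets of internal nodes) of a
    nested-tuple topology, excluding the root and the leaves."""
    out: set[frozenset[str]] = set()

    def walk(node: Topology, is_root: bool) -> list[str]:
        if isinstance(node, str):
            return [node]
        leaves: list[str] = []
        for child in node:
            leaves.extend(walk(child, False))
        if not is_root and len(leaves) > 1:
            out.add(frozenset(leaves))
        return leaves

    walk(topology, True)
    return out


def tree_mixture_means(topology: Topology,
                       displacements: Sequence[float],
                       f: int | None = None) -> tuple[list[str], np.ndarray]:
    """Place cluster means by recursive displacement along fresh axes.

    Each internal node at depth ``d`` spreads its children at
    ``±displacements[d]`` (evenly for >2 children) along a coordinate axis
    unique to that node, so sibling clusters end up closer to each other
    than to non-siblings whenever displacements decrease with depth.
    """
    names = _leaves(topology)
    axis_counter = {"next": 0}

    placements: dict[str, dict[int, float]] = {}

    def walk(node: Topology, depth: int, offset: dict[int, float]) -> None:
        if isinstance(node, str):
            placements[node] = dict(offset)
            return
        if depth >= len(displacements):
            raise ValueError(
                f"need a displacement for depth {depth} of the topology"
            )
        axis = axis_counter["next"]
        axis_counter["next"] += 1
        m = len(node)
        # symmetric offsets around the parent: -d, ..., +d
        coords = np.linspace(-1.0, 1.0, m) * displacements[depth]
        for child, c in zip(node, coords):
            child_offset = dict(offset)
            child_offset[axis] = child_offset.get(axis, 0.0) + c
            walk(child, depth + 1, child_offset)

    walk(topology, 0, {})
    n_axes = axis_counter["next"]
    dim = n_axes if f is None else f
    if dim < n_axes:
        raise ValueError(f"topology needs at least {n_axes} dimensions")
    means = np.zeros((len(names), dim))
    for i, name in enumerate(names):
        for axis, val in placements[name].items():
            means[i, axis] = val
    return names, means


def make_tree_mixture(topology: Topology,
                      displacements: Sequence[float],
                      sizes: Sequence[int] | int = 100,
                      sd: float = 1.0,
                      f: int | None = None,
                      seed: int = 0) -> tuple[Embedding, AttributeTable,
                                              MixtureSpec]:
    """Gaussian mixture whose cluster means follow a known tree topology.

    Returns the embedding, the true labels, and the fully resolved
    :class:`MixtureSpec` (with ``tree`` set to the generative topology).
    At ``sd=0`` every cell sits exactly on its cluster mean, so inter-cluster
    distances and the consensus dendrogram are fully determined by the
    placement geometry.
    """
    names, means = tree_mixture_means(topology, displacements, f=f)
    if np.isscalar(sizes):
        sizes = [int(sizes)] * len(names)
    spec = MixtureSpec(sizes=list(sizes), means=means, sd=sd, seed=seed,
                       names=names, tree=topology)
    emb, attrs = make_gaussian_mixture(spec)
    return emb, attrs, spec


def make_marker_attributes(labels: pd.Series,
                           n_markers: int = 1,
                           effect: float = 5.0,
                           sd: float = 1.0,
                           zero_inflation: float = 0.0,
                           seed: int = 0) -> AttributeTable:
    """Numeric per-cell attributes mimicking marker-gene expression.

    For every cluster label, ``n_markers`` columns are generated that are
    elevated by ``effect`` in exactly that cluster (baseline 0, Gaussian
    noise ``sd``).  With ``zero_inflation=p``, each value is independently
    zeroed with probability ``p``.
    """
    if not 0.0 <= zero_inflation <= 1.0:
        raise ValueError("zero_inflation must be in [0, 1]")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    labels = labels.astype(str)
    clusters = sorted(labels.unique())
    cols: dict[str, np.ndarray] = {}
    for cl in clusters:
        mask = (labels == cl).to_numpy()
        for m in range(n_markers):
            x = rng.standard_normal(len(labels)) * sd
            x[mask] += effect
            if zero_inflation > 0:
                x[rng.random(len(labels)) < zero_inflation] = 0.0
            cols[f"marker_{cl}_{m}"] = x
    df = pd.DataFrame(cols, index=labels.index)
    df.index.name = "cell_id"
    return AttributeTable(data=df, types={c: "numeric" for c in cols})
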