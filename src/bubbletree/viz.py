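"""Rendering: the bubble dendrogram and its stacked annotation panels.

All panels share one vertical axis: the tips of the tree, evenly spaced,
in dendrogram leaf order.  Bubbles are drawn with radii scaling linearly
in the cell count (anchored so the largest bubble has a fixed radius),
each labelled "id: n (pct%)"; internal branches carry their bootstrap
support counts.  Annotation panels (categorical tiles, numeric summary
tiles, violins, per-cell strips) are computed as plain matrices first so
their numbers can be audited independently of the figures.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import matplotlib
import numpy as np
import pandas as pd

matplotlib.use("Agg", force=False)
import matplotlib.pyplot as plt  # noqa: E402
from matplotlib.patches import Circle  # noqa: E402

from .io_model import ClusterAssignment, ValidationError
from .treebuild import BubbleTree

__all__ = [
    "TileMatrix",
    "plot_bubbletree",
    "get_cat_tiles",
    "get_num_tiles",
    "get_num_violins",
    "get_num_cell_tiles",
    "compare_bubbletrees",
]

_SUMMARIES = ("mean", "median", "sum", "pct_nonzero", "pct_zero")


@dataclass
class TileMatrix:
    """Bubbles × categories (or features) summary matrix behind a panel.

    Rows follow the tree's tip order.  ``normalization`` records how the
    values integrate: ``within_bubble`` rows sum to 100, ``across_bubbles``
    columns sum to 100, ``none`` for raw summaries.  Printed annotations
    are rounded to the nearest tenth; stored values keep full precision.
    """

    values: pd.DataFrame
    normalization: str = "none"

    def __post_init__(self) -> None:
        if self.normalization not in ("within_bubble", "across_bubbles",
                                      "none"):
            raise ValueError(
                f"unknown normalization {self.normalization!r}"
            )

    @property
    def annotations(self) -> pd.DataFrame:
        return self.values.round(1)

    def to_csv(self, path) -> None:
        self.values.to_csv(path)

    def plot(self, ax=None, cmap: str = "viridis", annotate: bool = True,
             tile_text_color: str = "w"):
        """Heatmap of the matrix with rounded value annotations."""
        if ax is None:
            _, ax = plt.subplots(
                figsize=(1 + 0.6 * self.values.shape[1],
                         1 + 0.4 * self.values.shape[0])
            )
        vals = self.values.to_numpy(dtype=float)
        ax.pcolormesh(np.ma.masked_invalid(vals), cmap=cmap)
        if annotate:
            ann = self.annotations.to_numpy()
            for i in range(vals.shape[0]):
                for j in range(vals.shape[1]):
                    txt = "NA" if np.isnan(vals[i, j]) else f"{ann[i, j]:g}"
                    ax.text(j + 0.5, i + 0.5, txt, ha="center",
                            va="center", fontsize=7, color=tile_text_color)
        ax.set_xticks(np.arange(vals.shape[1]) + 0.5,
                      [str(c) for c in self.values.columns], rotation=90)
        ax.set_yticks(np.arange(vals.shape[0]) + 0.5,
                      [str(r) for r in self.values.index])
        ax.invert_yaxis()
        return ax


def _cells_per_tip(tree: BubbleTree,
                   assignment: ClusterAssignment | None) -> dict[str, list[str]]:
    a = assignment or tree.assignment
    if a is None:
        raise ValidationError(
            "no cell assignment attached to the tree; pass assignment="
        )
    members = a.members()
    missing = [t for t in tree.tip_ids if t not in members]
    if missing:
        raise ValidationError(f"tree tips without cells: {missing}")
    return members


def get_cat_tiles(tree: BubbleTree, labels: pd.Series,
                  integrate_vertical: bool = False,
                  assignment: ClusterAssignment | None = None) -> TileMatrix:
    """Categorical composition tiles.

    ``integrate_vertical=True``: tile(i, j) is the percentage of all
    label-j cells that sit in bubble i (columns sum to 100) — where is a
    label enriched?  ``False``: tile(i, j) is the percentage of bubble
    i's cells carrying label j (rows sum to 100) — what is a bubble made
    of?
    """
    members = _cells_per_tip(tree, assignment)
    order = tree.tip_order()
    labels = labels.astype(str)
    cats = sorted(labels.unique())
    counts = pd.DataFrame(0.0, index=order, columns=cats)
    for tip in order:
        vc = labels.reindex(members[tip]).dropna().value_counts()
        counts.loc[tip, vc.index] = vc.to_numpy(dtype=float)
    absent = [c for c in cats if counts[c].sum() == 0]
    if absent:
        warnings.warn(f"labels absent from every bubble dropped: {absent}",
                      stacklevel=2)
        counts = counts.drop(columns=absent)
    if integrate_vertical:
        vals = 100.0 * counts / counts.sum(axis=0)
        norm = "across_bubbles"
    else:
        vals = 100.0 * counts.div(counts.sum(axis=1), axis=0)
        norm = "within_bubble"
    vals.index.name = "bubble"
    return TileMatrix(values=vals, normalization=norm)


def get_num_tiles(tree: BubbleTree, features: pd.DataFrame,
                  summary: str = "mean",
                  assignment: ClusterAssignment | None = None) -> TileMatrix:
    """Per-bubble statistical summaries of numeric cell attributes.

    ``summary`` is one of mean, median, sum, pct_nonzero, pct_zero; a
    bubble in which a feature is entirely missing yields a NaN tile.
    """
    if summary not in _SUMMARIES:
        raise ValueError(f"unknown summary {summary!r}; use {_SUMMARIES}")
    members = _cells_per_tip(tree, assignment)
    order = tree.tip_order()
    out = pd.DataFrame(np.nan, index=order, columns=list(features.columns))
    for tip in order:
        sub = features.reindex(members[tip])
        for col in features.columns:
            x = sub[col].dropna().to_numpy(dtype=float)
            if x.size == 0:
                continue
            if summary == "mean":
                out.loc[tip, col] = x.mean()
            elif summary == "median":
                out.loc[tip, col] = float(np.median(x))
            elif summary == "sum":
                out.loc[tip, col] = x.sum()
            elif summary == "pct_nonzero":
                out.loc[tip, col] = 100.0 * (x != 0).mean()
            else:
                out.loc[tip, col] = 100.0 * (x == 0).mean()
    out.index.name = "bubble"
    return TileMatrix(values=out, normalization="none")


# -- dendrogram drawing ------------------------------------------------------

def _node_positions(tree: BubbleTree) -> tuple[dict[int, float],
                                               dict[int, float]]:
    """x (height) and y (leaf-order) coordinate of every linkage node."""
    k = tree.k
    order = tree.tip_order()
    ypos_tip = {tree.tip_ids.index(t): float(i) for i, t in enumerate(order)}
    x: dict[int, float] = {i: 0.0 for i in range(k)}
    y: dict[int, float] = dict(ypos_tip)
    for m, (a, b, h, _) in enumerate(tree.linkage):
        node = k + m
        x[node] = float(h)
        y[node] = 0.5 * (y[int(a)] + y[int(b)])
    return x, y


def plot_bubbletree(tree: BubbleTree, ax=None, max_radius: float = 0.35,
                    show_support: bool = True, path=None,
                    orientation: str = "horizontal"):
    """Draw the consensus dendrogram with bubbles at the tips.

    Horizontal layout: merge heights run along x (root at the maximum
    height, tips at 0), tips are evenly spaced along y, so root-to-leaf
    path lengths encode the bootstrap distance structure while the
    vertical spacing carries no meaning.  Bubble radii are linear in the
    cell count, anchored at ``max_radius`` (y-axis units) for the largest
    bubble.
    """
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 1 + 0.45 * tree.k))
    x, y = _node_positions(tree)
    k = tree.k

    def seg(x0, y0, x1, y1):
        if orientation == "horizontal":
            ax.plot([x0, x1], [y0, y1], color="k", lw=1)
        else:
            ax.plot([y0, y1], [x0, x1], color="k", lw=1)

    for m, (a, b, h, _) in enumerate(tree.linkage):
        a, b = int(a), int(b)
        seg(h, y[a], x[a], y[a])
        seg(h, y[b], x[b], y[b])
        seg(h, y[a], h, y[b])
        if show_support and tree.support is not None:
            if orientation == "horizontal":
                ax.annotate(str(int(tree.support[m])), (h, (y[a] + y[b]) / 2),
                            fontsize=7, color="gray",
                            textcoords="offset points", xytext=(2, 2))
            else:
                ax.annotate(str(int(tree.support[m])), ((y[a] + y[b]) / 2, h),
                            fontsize=7, color="gray",
                            textcoords="offset points", xytext=(2, 2))

    n_total = tree.n_total
    cmax = tree.counts.max()
    root_h = float(tree.linkage[:, 2].max())
    for i, tip in enumerate(tree.tip_ids):
        r = max_radius * tree.counts[i] / cmax
        center = ((0.0, y[i]) if orientation == "horizontal"
                  else (y[i], 0.0))
        ax.add_patch(Circle(center, radius=r, facecolor="white",
                            edgecolor="k", zorder=3))
        pct = 100.0 * tree.counts[i] / n_total
        label = f"{tip}: {tree.counts[i]:,} ({pct:.1f}%)"
        if orientation == "horizontal":
            ax.annotate(label, (0.0, y[i]), fontsize=8,
                        textcoords="offset points",
                        xytext=(-8, 0), ha="right", va="center")
        else:
            ax.annotate(label, (y[i], 0.0), fontsize=8, rotation=90,
                        textcoords="offset points",
                        xytext=(0, -8), ha="center", va="top")

    if orientation == "horizontal":
        ax.set_xlim(root_h * 1.05 if root_h > 0 else 1.0, -root_h * 0.45 - 1)
        ax.set_ylim(-0.8, k - 0.2)
        ax.set_xlabel("inter-bubble distance")
        ax.set_yticks([])
    else:
        ax.set_ylim(-root_h * 0.45 - 1, root_h * 1.05 if root_h > 0 else 1.0)
        ax.set_xlim(-0.8, k - 0.2)
        ax.set_ylabel("inter-bubble distance")
        ax.set_xticks([])
        ax.invert_yaxis()
    for side in ("top", "right", "left" if orientation == "horizontal"
                 else "bottom"):
        ax.spines[side].set_visible(False)
    if path is not None:
        ax.figure.savefig(path, bbox_inches="tight", dpi=150)
    return ax


def get_num_violins(tree: BubbleTree, features: pd.DataFrame,
                    assignment: ClusterAssignment | None = None,
                    path=None):
    """Distributions of numeric attributes per bubble as violin panels.

    One column of axes per feature; rows (violin positions) follow the
    tree's tip order.  Bubbles with fewer than 2 values, or no spread,
    are drawn as points.  Bandwidth follows Scott's rule.
    """
    members = _cells_per_tip(tree, assignment)
    order = tree.tip_order()
    ncol = features.shape[1]
    fig, axes = plt.subplots(
        1, ncol, figsize=(2.2 * ncol, 1 + 0.4 * len(order)),
        sharey=True, squeeze=False,
    )
    for j, col in enumerate(features.columns):
        ax = axes[0, j]
        for i, tip in enumerate(order):
            x = features[col].reindex(members[tip]).dropna().to_numpy(float)
            if x.size >= 2 and np.ptp(x) > 0:
                ax.violinplot([x], positions=[i], orientation="horizontal",
                              widths=0.8, bw_method="scott",
                              showextrema=False)
            elif x.size:
                ax.plot(x.mean(), i, "o", ms=3, color="C0")
        ax.set_title(str(col), fontsize=9)
        if j == 0:
            ax.set_yticks(range(len(order)), order)
        ax.invert_yaxis() if j == 0 else None
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, bbox_inches="tight", dpi=150)
    return fig


def get_num_cell_tiles(tree: BubbleTree, feature: pd.Series,
                       assignment: ClusterAssignment | None = None,
                       order: str = "descending",
                       path=None):
    """Per-cell heatmap strips, one row per bubble, cells sorted by value.

    Each bubble's cells are laid out left-to-right in ``order`` of the
    attribute, stretched to a common strip width so within-bubble rank
    position is comparable across bubbles of unequal size.
    """
    if order not in ("descending", "ascending"):
        raise ValueError("order must be 'descending' or 'ascending'")
    members = _cells_per_tip(tree, assignment)
    tips = tree.tip_order()
    width = 256
    strips = np.full((len(tips), width), np.nan)
    allvals = feature.dropna().to_numpy(float)
    vmin, vmax = (allvals.min(), allvals.max()) if allvals.size else (0, 1)
    for i, tip in enumerate(tips):
        x = np.sort(feature.reindex(members[tip]).dropna().to_numpy(float))
        if order == "descending":
            x = x[::-1]
        if x.size:
            idx = np.minimum((np.arange(width) * x.size) // width, x.size - 1)
            strips[i] = x[idx]
    fig, ax = plt.subplots(figsize=(5, 1 + 0.3 * len(tips)))
    ax.imshow(np.ma.masked_invalid(strips), aspect="auto",
              interpolation="nearest", vmin=vmin, vmax=vmax, cmap="viridis")
    ax.set_yticks(range(len(tips)), tips)
    ax.set_xticks([])
    ax.set_xlabel(f"cells ordered by {feature.name} ({order})")
    if path is not None:
        fig.savefig(path, bbox_inches="tight", dpi=150)
    return fig


def compare_bubbletrees(t1: BubbleTree, t2: BubbleTree,
                        a1: ClusterAssignment | None = None,
                        a2: ClusterAssignment | None = None,
                        path=None) -> tuple[object, TileMatrix]:
    """Two trees built from the same cells, joined by a contingency matrix.

    The k1×k2 matrix counts cells shared between cluster pairs; rows and
    columns follow each tree's tip order.  The first tree is drawn on the
    left (tips facing the matrix rows), the second on top (tips facing
    the matrix columns).
    """
    a1 = a1 or t1.assignment
    a2 = a2 or t2.assignment
    if a1 is None or a2 is None:
        raise ValidationError("both trees need cell assignments")
    if set(a1.cell_ids) != set(a2.cell_ids):
        raise ValidationError("the two trees cover different cell sets")
    s1 = a1.as_series()
    s2 = a2.as_series().reindex(s1.index)
    ct = pd.crosstab(s1, s2)
    rows, cols = t1.tip_order(), t2.tip_order()
    ct = ct.reindex(index=rows, columns=cols).fillna(0).astype(int)
    ct.index.name = "bubble_1"
    ct.columns.name = "bubble_2"
    tiles = TileMatrix(values=ct.astype(float), normalization="none")

    fig = plt.figure(figsize=(3 + 0.4 * t2.k, 3 + 0.4 * t1.k))
    gs = fig.add_gridspec(2, 2, width_ratios=[1.2, 0.4 * t2.k],
                          height_ratios=[1.2, 0.4 * t1.k],
                          hspace=0.05, wspace=0.05)
    ax_t2 = fig.add_subplot(gs[0, 1])
    plot_bubbletree(t2, ax=ax_t2, orientation="vertical", show_support=False)
    ax_t1 = fig.add_subplot(gs[1, 0])
    plot_bubbletree(t1, ax=ax_t1, orientation="horizontal",
                    show_support=False)
    ax_ct = fig.add_subplot(gs[1, 1])
    tiles.plot(ax=ax_ct, annotate=t1.k * t2.k <= 400)
    ax_ct.invert_yaxis()  # undo TileMatrix.plot inversion; rows align to t1
    if path is not None:
        fig.savefig(path, bbox_inches="tight", dpi=150)
    return fig, tiles
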