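"""Core data containers and on-disk formats.

The toolkit consumes a finished low-dimensional embedding (e.g. PCA scores)
of n cells in f dimensions; it is agnostic about how that embedding was
produced.  Cell identifiers are strings, the row order of the embedding
file is the canonical cell order, and attribute tables are always joined
by id, never by position.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Mapping, Sequence

import numpy as np
import pandas as pd

if TYPE_CHECKING:  # pragma: no cover
    from .treebuild import BubbleTree

__all__ = [
    "Embedding",
    "AttributeTable",
    "ClusterAssignment",
    "ValidationError",
    "read_embedding",
    "read_attributes",
    "write_tree",
    "read_tree",
]


class ValidationError(ValueError):
    """Input violates a structural invariant (duplicate ids, NaNs, ...)."""


@dataclass
class Embedding:
    """An ``n x f`` numeric matrix of cells in a low-dimensional feature space.

    Parameters
    ----------
    cell_ids
        Unique string identifier per cell (row).
    matrix
        Real-valued array of shape ``(n, f)``; no missing or non-finite
        entries are allowed.
    feature_names
        One name per column; generated as ``f0..f{f-1}`` when omitted.
    """

    cell_ids: list[str]
    matrix: np.ndarray
    feature_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2:
            raise ValidationError("embedding matrix must be 2-dimensional")
        n, f = self.matrix.shape
        if n < 2:
            raise ValidationError(f"embedding needs at least 2 cells, got {n}")
        if f < 1:
            raise ValidationError("embedding needs at least 1 feature")
        self.cell_ids = [str(c) for c in self.cell_ids]
        if len(self.cell_ids) != n:
            raise ValidationError(
                f"{len(self.cell_ids)} cell ids for {n} matrix rows"
            )
        dupes = _duplicates(self.cell_ids)
        if dupes:
            raise ValidationError(f"duplicate cell ids: {sorted(dupes)}")
        if not np.isfinite(self.matrix).all():
            bad = np.argwhere(~np.isfinite(self.matrix))
            raise ValidationError(
                f"non-finite values at (row, col) {bad[:5].tolist()}"
            )
        if not self.feature_names:
            self.feature_names = [f"f{i}" for i in range(f)]
        elif len(self.feature_names) != f:
            raise ValidationError(
                f"{len(self.feature_names)} feature names for {f} columns"
            )

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    @property
    def f(self) -> int:
        return self.matrix.shape[1]

    def index_of(self, cell_ids: Sequence[str]) -> np.ndarray:
        """Row indices of the given cells, in the given order."""
        pos = {c: i for i, c in enumerate(self.cell_ids)}
        missing = [c for c in cell_ids if c not in pos]
        if missing:
            raise ValidationError(f"unknown cell ids: {missing[:10]}")
        return np.array([pos[c] for c in cell_ids], dtype=int)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.matrix, index=pd.Index(self.cell_ids, name="cell_id"),
            columns=self.feature_names,
        )

    def to_csv(self, path, delimiter: str = ",") -> None:
        self.to_frame().to_csv(path, sep=delimiter)


@dataclass
class AttributeTable:
    """Per-cell annotations (numeric or categorical), keyed by cell id.

    ``data`` is indexed by cell id; ``types`` maps each column to
    ``"numeric"`` or ``"categorical"``.  Numeric columns may contain
    missing values (NaN); categorical columns are strings.
    """

    data: pd.DataFrame
    types: dict[str, str]

    def __post_init__(self) -> None:
        for col, t in self.types.items():
            if t not in ("numeric", "categorical"):
                raise ValidationError(f"column {col!r}: unknown type {t!r}")
            if col not in self.data.columns:
                raise ValidationError(f"declared column {col!r} not in table")

    @property
    def cell_ids(self) -> list[str]:
        return list(self.data.index)

    def column(self, name: str) -> pd.Series:
        if name not in self.data.columns:
            raise KeyError(name)
        return self.data[name]

    def numeric(self, names: Sequence[str] | None = None) -> pd.DataFrame:
        cols = [c for c, t in self.types.items() if t == "numeric"]
        if names is not None:
            bad = [c for c in names if c not in cols]
            if bad:
                raise ValidationError(f"not numeric columns: {bad}")
            cols = list(names)
        return self.data[cols]


@dataclass
class ClusterAssignment:
    """A hard partition of the cells into k labelled clusters."""

    cell_ids: list[str]
    labels: list[str]

    def __post_init__(self) -> None:
        self.cell_ids = [str(c) for c in self.cell_ids]
        self.labels = [str(l) for l in self.labels]
        if len(self.cell_ids) != len(self.labels):
            raise ValidationError(
                f"{len(self.labels)} labels for {len(self.cell_ids)} cells"
            )
        if _duplicates(self.cell_ids):
            raise ValidationError("duplicate cell ids in assignment")
        if any(l == "" for l in self.labels):
            raise ValidationError("empty cluster label")

    @property
    def n(self) -> int:
        return len(self.cell_ids)

    @property
    def k(self) -> int:
        return len(set(self.labels))

    @property
    def cluster_ids(self) -> list[str]:
        """Distinct labels, ordered by decreasing cluster size (ties: label)."""
        counts = self.counts()
        return list(counts.index)

    def counts(self) -> pd.Series:
        s = pd.Series(self.labels, dtype=object).value_counts()
        # deterministic: size desc, then label asc
        return s.sort_index().sort_values(ascending=False, kind="stable")

    def as_series(self) -> pd.Series:
        return pd.Series(
            self.labels, index=pd.Index(self.cell_ids, name="cell_id"),
            name="cluster",
        )

    def members(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {l: [] for l in self.cluster_ids}
        for c, l in zip(self.cell_ids, self.labels):
            out[l].append(c)
        return out


def _duplicates(items: Sequence[str]) -> set[str]:
    seen: set[str] = set()
    dup: set[str] = set()
    for x in items:
        if x in seen:
            dup.add(x)
        seen.add(x)
    return dup


def read_embedding(path, id_column: str = "cell_id",
                   delimiter: str = ",") -> Embedding:
    """Read a delimited text file into an :class:`Embedding`.

    The file must have a header row; every non-id column must parse as a
    number.  Rows keep file order.
    """
    df = pd.read_csv(path, sep=delimiter, dtype={0: str},
                     float_precision="round_trip")
    if id_column not in df.columns:
        raise ValidationError(
            f"id column {id_column!r} not found in {list(df.columns)}"
        )
    ids = df[id_column].astype(str).tolist()
    dupes = _duplicates(ids)
    if dupes:
        raise ValidationError(f"duplicate cell ids in {path}: {sorted(dupes)}")
    feats = [c for c in df.columns if c != id_column]
    mat = np.empty((len(df), len(feats)), dtype=float)
    for j, c in enumerate(feats):
        col = pd.to_numeric(df[c], errors="coerce")
        bad = col.index[col.isna() & df[c].notna()]
        if len(bad) or col.isna().any():
            row = int(bad[0]) if len(bad) else int(col.index[col.isna()][0])
            raise ValidationError(
                f"non-numeric value in column {c!r}, row {row} "
                f"(cell {ids[row]!r})"
            )
        mat[:, j] = col.to_numpy()
    return Embedding(cell_ids=ids, matrix=mat, feature_names=feats)


def read_attributes(path, id_column: str = "cell_id",
                    types: Mapping[str, str] | None = None,
                    reference: Embedding | None = None,
                    delimiter: str = ",") -> AttributeTable:
    """Read per-cell attributes and (optionally) validate against an embedding.

    ``types`` declares each column ``numeric`` or ``categorical``; undeclared
    columns are inferred (object dtype -> categorical).  With ``reference``
    given, the table must cover exactly the embedding's cells: unknown ids
    and uncovered embedding ids are both errors.
    """
    df = pd.read_csv(path, sep=delimiter, float_precision="round_trip")
    if id_column not in df.columns:
        raise ValidationError(f"id column {id_column!r} not found")
    df[id_column] = df[id_column].astype(str)
    if _duplicates(df[id_column].tolist()):
        raise ValidationError("duplicate cell ids in attribute table")
    df = df.set_index(id_column)
    df.index.name = "cell_id"

    decided: dict[str, str] = dict(types or {})
    for c in df.columns:
        if c not in decided:
            decided[c] = (
                "numeric" if pd.api.types.is_numeric_dtype(df[c])
                else "categorical"
            )
    for c, t in decided.items():
        if c not in df.columns:
            raise ValidationError(f"declared column {c!r} not in file")
        if t == "numeric":
            coerced = pd.to_numeric(df[c], errors="coerce")
            text = coerced.isna() & df[c].notna() & ~df[c].astype(str).isin(
                ["NA", "NaN", "nan", ""]
            )
            if text.any():
                raise ValidationError(
                    f"numeric column {c!r} has non-numeric value at cell "
                    f"{df.index[text.argmax()]!r}"
                )
            df[c] = coerced
        else:
            df[c] = df[c].astype(object).where(df[c].notna(), other=np.nan)
            df[c] = df[c].map(lambda v: v if pd.isna(v) else str(v))

    if reference is not None:
        ref = set(reference.cell_ids)
        extra = [c for c in df.index if c not in ref]
        if extra:
            raise ValidationError(
                f"attribute ids absent from embedding: {extra[:10]}"
            )
        missing = [c for c in reference.cell_ids if c not in set(df.index)]
        if missing:
            raise ValidationError(
                f"embedding cells not covered by attribute table: "
                f"{missing[:10]}"
            )
        df = df.loc[reference.cell_ids]
    return AttributeTable(data=df, types=decided)


# -- tree persistence --------------------------------------------------------

def write_tree(tree: "BubbleTree", path, format: str = "newick") -> None:
    """Serialize a bubble tree as Newick or as a JSON analysis bundle.

    Newick: tips are bubble ids, branch lengths are merge-height
    differences, internal-node labels are bootstrap support counts.
    JSON additionally stores the mean distance matrix, per-bubble cell
    counts and the run configuration.
    """
    if format == "newick":
        with open(path, "w") as fh:
            fh.write(tree.to_newick() + "\n")
    elif format == "json":
        bundle = {
            "newick": tree.to_newick(),
            "cluster_ids": list(tree.tip_ids),
            "counts": {t: int(c) for t, c in zip(tree.tip_ids, tree.counts)},
            "mean_distance": None if tree.mean_distance is None
            else np.asarray(tree.mean_distance).tolist(),
            "support": None if tree.support is None
            else [int(s) for s in tree.support],
            "b_iterations": tree.b_iterations,
            "config": tree.config,
        }
        with open(path, "w") as fh:
            json.dump(bundle, fh, indent=1)
    else:
        raise ValueError(f"unknown tree format {format!r}")


def read_tree(path, format: str = "newick") -> "BubbleTree":
    """Inverse of :func:`write_tree` (topology, heights, supports)."""
    from .treebuild import BubbleTree

    if format == "newick":
        with open(path) as fh:
            return BubbleTree.from_newick(fh.read())
    if format == "json":
        with open(path) as fh:
            bundle = json.load(fh)
        tree = BubbleTree.from_newick(bundle["newick"])
        tree.counts = np.array(
            [bundle["counts"][t] for t in tree.tip_ids], dtype=int
        )
        if bundle.get("mean_distance") is not None:
            stored = np.asarray(bundle["mean_distance"], float)
            perm = [bundle["cluster_ids"].index(t) for t in tree.tip_ids]
            tree.mean_distance = stored[np.ix_(perm, perm)]
        tree.b_iterations = bundle.get("b_iterations")
        tree.config = bundle.get("config")
        return tree
    raise ValueError(f"unknown tree format {format!r}")
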