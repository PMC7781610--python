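"""Reading, writing and elementary transforms of connectome matrices.

The central data structure is :class:`ConnectomeGraph`, a weighted directed
adjacency matrix (rows = source areas, columns = target areas) with node
labels, optional 3D coordinates and free-form provenance metadata.

Input files are delimited labeled matrices (CSV or TSV).  Missing entries
(empty cells or ``NA``) mean "connection not tested" and are distinct from
literal ``0``, which means "tested, absent".  The ``pairwise_complete``
loader flag drops nodes that carry any untested entry.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

__all__ = [
    "ConnectomeGraph",
    "LengthMatrix",
    "load_connectome",
    "save_connectome",
    "weight_to_length",
    "symmetrize",
    "interareal_distances",
]

#: strings interpreted as "not tested" in matrix files
NA_SENTINELS = ("", "NA", "NaN", "nan", "N/A")


class ConnectomeError(ValueError):
    """Raised when a matrix violates the connectome invariants."""


@dataclass
class ConnectomeGraph:
    """Weighted directed graph of inter-areal connections.

    Parameters
    ----------
    weights
        n x n nonnegative matrix; ``weights[i, j]`` is the weight of the
        projection from area ``i`` (source) to area ``j`` (target).
    labels
        Unique area names, length n.
    coords
        Optional n x 3 injection-centroid coordinates in mm.
    meta
        Free-form provenance dictionary.
    fraction_weights
        If True, weights are fractions and must not exceed 1.
    """

    weights: np.ndarray
    labels: Sequence[str]
    coords: Optional[np.ndarray] = None
    meta: dict = field(default_factory=dict)
    fraction_weights: bool = False

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.labels = list(map(str, self.labels))
        if self.weights.ndim != 2 or self.weights.shape[0] != self.weights.shape[1]:
            raise ConnectomeError(f"matrix must be square, got shape {self.weights.shape}")
        n = self.weights.shape[0]
        if len(self.labels) != n:
            raise ConnectomeError(f"{len(self.labels)} labels for {n} nodes")
        if len(set(self.labels)) != n:
            raise ConnectomeError("labels are not unique")
        if not np.all(np.isfinite(self.weights)):
            raise ConnectomeError("weights contain non-finite values")
        if np.any(self.weights < 0):
            raise ConnectomeError("negative weight found")
        if np.any(np.diag(self.weights) != 0):
            raise ConnectomeError("diagonal must be exactly zero (no self-loops)")
        if self.fraction_weights and np.any(self.weights > 1):
            raise ConnectomeError("fractional weights must lie in [0, 1]")
        if self.coords is not None:
            self.coords = np.asarray(self.coords, dtype=float)
            if self.coords.shape != (n, 3):
                raise ConnectomeError(f"coords must be ({n}, 3), got {self.coords.shape}")
            if not np.all(np.isfinite(self.coords)):
                raise ConnectomeError("coords contain non-finite values")

    # -- basic accessors -------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]

    @property
    def n_edges(self) -> int:
        """Number of directed edges (strictly positive off-diagonal entries)."""
        return int(np.count_nonzero(self.weights))

    @property
    def density_directed(self) -> float:
        n = self.n_nodes
        return self.n_edges / (n * (n - 1))

    @property
    def density_undirected(self) -> float:
        und = (self.weights > 0) | (self.weights.T > 0)
        n = self.n_nodes
        return np.count_nonzero(np.triu(und, 1)) / (n * (n - 1) / 2)

    def binary(self) -> np.ndarray:
        """0/1 adjacency matrix."""
        return (self.weights > 0).astype(int)

    def copy(self) -> "ConnectomeGraph":
        return ConnectomeGraph(
            self.weights.copy(),
            list(self.labels),
            None if self.coords is None else self.coords.copy(),
            dict(self.meta),
            self.fraction_weights,
        )

    def with_weights(self, weights: np.ndarray, **meta) -> "ConnectomeGraph":
        """New graph with the same labels/coords but different weights."""
        return ConnectomeGraph(
            np.asarray(weights, dtype=float),
            list(self.labels),
            None if self.coords is None else self.coords.copy(),
            {**self.meta, **meta},
            self.fraction_weights,
        )


@dataclass
class LengthMatrix:
    """Edge lengths derived from weights; ``inf`` marks an absent edge."""

    lengths: np.ndarray
    labels: Sequence[str]

    def __post_init__(self) -> None:
        self.lengths = np.asarray(self.lengths, dtype=float)
        if np.any(self.lengths < 0):
            raise ConnectomeError("negative length")


def _read_matrix(path: Path) -> pd.DataFrame:
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df = pd.read_csv(
        path,
        sep=sep,
        index_col=0,
        na_values=list(NA_SENTINELS),
        keep_default_na=False,
        float_precision="round_trip",
    )
    df.index = df.index.map(str)
    df.columns = df.columns.map(str)
    return df


def load_connectome(
    weights_path,
    coords_path=None,
    pairwise_complete: bool = False,
    fraction_weights: bool = True,
) -> ConnectomeGraph:
    """Load a labeled weight matrix (and optional coordinates) from disk.

    Rows are source areas and columns are target areas; both carry labels
    and must agree.  With ``pairwise_complete=True``, nodes whose row or
    column contains a missing-value sentinel are dropped iteratively (the
    node with most missing entries first) until the remaining submatrix is
    complete.

    Raises
    ------
    ConnectomeError
        On a non-square matrix, negative weight, nonzero diagonal, label
        mismatch between rows and columns or between matrix and coordinate
        files, or residual missing values when ``pairwise_complete`` is off.
    """
    weights_path = Path(weights_path)
    df = _read_matrix(weights_path)
    if df.shape[0] != df.shape[1]:
        raise ConnectomeError(f"matrix in {weights_path} is not square: {df.shape}")
    if list(df.index) != list(df.columns):
        raise ConnectomeError("row labels differ from column labels")

    if pairwise_complete:
        while df.isna().to_numpy().any():
            miss = df.isna().to_numpy()
            per_node = miss.sum(axis=1) + miss.sum(axis=0)
            worst = int(np.argmax(per_node))
            keep = [i for i in range(df.shape[0]) if i != worst]
            df = df.iloc[keep, keep]
    elif df.isna().to_numpy().any():
        raise ConnectomeError(
            "matrix contains missing values; pass pairwise_complete=True to drop them"
        )

    labels = list(df.index)
    weights = df.to_numpy(dtype=float)

    coords = None
    if coords_path is not None:
        cdf = pd.read_csv(Path(coords_path), float_precision="round_trip")
        cdf.iloc[:, 0] = cdf.iloc[:, 0].map(str)
        cdf = cdf.set_index(cdf.columns[0])
        missing = [lab for lab in labels if lab not in cdf.index]
        if missing:
            raise ConnectomeError(f"coords file lacks rows for labels: {missing}")
        coords = cdf.loc[labels].iloc[:, :3].to_numpy(dtype=float)

    meta = {"source": str(weights_path), "pairwise_complete": pairwise_complete}
    return ConnectomeGraph(weights, labels, coords, meta, fraction_weights)


def save_connectome(g: ConnectomeGraph, weights_path, coords_path=None, meta_path=None) -> None:
    """Write the weight matrix (and optionally coordinates and metadata)."""
    weights_path = Path(weights_path)
    sep = "\t" if weights_path.suffix.lower() in (".tsv", ".tab") else ","
    df = pd.DataFrame(g.weights, index=g.labels, columns=g.labels)
    df.to_csv(weights_path, sep=sep, float_format="%.17g")
    if coords_path is not None:
        if g.coords is None:
            raise ConnectomeError("graph has no coordinates to save")
        cdf = pd.DataFrame(g.coords, columns=["x", "y", "z"])
        cdf.insert(0, "label", g.labels)
        cdf.to_csv(coords_path, index=False, float_format="%.17g")
    if meta_path is not None:
        Path(meta_path).write_text(json.dumps(g.meta, indent=2, default=str))


def weight_to_length(g: ConnectomeGraph) -> LengthMatrix:
    """Map weights to lengths via ``-ln(w / w_max)``.

    Large weights become short lengths; the maximum weight maps to length
    exactly 0 and absent edges to ``inf``.  The transform is strictly
    order-reversing on the positive-weight support.
    """
    w = g.weights
    wmax = w.max()
    if wmax <= 0:
        raise ConnectomeError("all-zero matrix has no length transform")
    lengths = np.full_like(w, np.inf)
    pos = w > 0
    lengths[pos] = -np.log(w[pos] / wmax)
    # -log of the max itself can come out as -0.0
    lengths[pos] = np.maximum(lengths[pos], 0.0)
    np.fill_diagonal(lengths, 0.0)
    return LengthMatrix(lengths, list(g.labels))


def symmetrize(g: ConnectomeGraph, rule: str = "max") -> ConnectomeGraph:
    """Undirected version of the graph, stored as a symmetric matrix.

    ``max``/``mean`` combine the two directed weights; ``or-binary`` sets
    an entry to 1 iff either direction is nonzero.
    """
    w = g.weights
    if rule == "max":
        sym = np.maximum(w, w.T)
    elif rule == "mean":
        present = (w > 0) | (w.T > 0)
        sym = np.where(present, (w + w.T) / 2.0, 0.0)
    elif rule == "or-binary":
        sym = ((w > 0) | (w.T > 0)).astype(float)
    else:
        raise ValueError(f"unknown symmetrization rule {rule!r}")
    out = g.with_weights(sym, symmetrized=rule)
    if rule == "or-binary":
        out.fraction_weights = True
    return out


def interareal_distances(coords: np.ndarray) -> np.ndarray:
    """Pairwise Euclidean distances between injection centroids (mm)."""
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 3:
        raise ConnectomeError(f"coords must be (n, 3), got {coords.shape}")
    if not np.all(np.isfinite(coords)):
        raise ConnectomeError("coords contain non-finite values")
    return cdist(coords, coords)
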