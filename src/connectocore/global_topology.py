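"""Node- and graph-level statistics with null-normalized small-world indices.

Conventions: the weight matrix is oriented rows = source, columns = target,
so ``s_out`` is a row sum and ``s_in`` a column sum.  Reciprocity is the
correlation between the off-diagonal weight matrix and its transpose;
clustering is the weighted-directed (Fagiolo) form on max-normalized
weights; the characteristic path length runs Dijkstra on the logarithmic
weight-to-length transform.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import dijkstra

from .io import ConnectomeGraph, LengthMatrix, weight_to_length
from .nulls import NullEnsemble

__all__ = [
    "StrengthVector",
    "GlobalMetrics",
    "SmallWorldIndices",
    "strengths",
    "reciprocity",
    "assortativity",
    "clustering_coefficient",
    "characteristic_path_length",
    "shortest_path_matrix",
    "small_world",
    "global_metrics",
]


@dataclass
class StrengthVector:
    s_in: np.ndarray
    s_out: np.ndarray
    k_in: np.ndarray
    k_out: np.ndarray

    @property
    def total_strength(self) -> np.ndarray:
        return self.s_in + self.s_out

    @property
    def total_degree(self) -> np.ndarray:
        return self.k_in + self.k_out


@dataclass
class GlobalMetrics:
    density_directed: float
    density_undirected: float
    reciprocity: float
    assortativity_degree: float
    assortativity_strength: float
    clustering_mean: float
    char_path_length: float
    n_nodes: int
    n_edges: int


@dataclass
class SmallWorldIndices:
    """Null-normalized clustering (gamma), path length (lambda) and sigma."""

    gamma_norm: float
    lambda_norm: float
    sigma: float
    null_clustering: np.ndarray
    null_path_length: np.ndarray


def strengths(g: ConnectomeGraph) -> StrengthVector:
    """In/out strengths (weighted) and degrees (binary) per node."""
    w = g.weights
    a = g.binary()
    return StrengthVector(
        s_in=w.sum(axis=0),
        s_out=w.sum(axis=1),
        k_in=a.sum(axis=0),
        k_out=a.sum(axis=1),
    )


def reciprocity(g: ConnectomeGraph) -> float:
    """Correlation between the off-diagonal weight matrix and its transpose.

    Both samples share the same mean and variance (they are permutations of
    each other), so this is a plain Pearson correlation of ``w_ij`` with
    ``w_ji`` over all ordered pairs i != j.  Returns NaN when the
    off-diagonal entries have zero variance.
    """
    w = g.weights
    mask = ~np.eye(g.n_nodes, dtype=bool)
    x = w[mask]
    y = w.T[mask]
    wbar = x.mean()
    denom = np.sum((x - wbar) ** 2)
    if denom == 0:
        return float("nan")
    return float(np.sum((x - wbar) * (y - wbar)) / denom)


def assortativity(g: ConnectomeGraph, mode: str = "degree") -> float:
    """Pearson correlation of endpoint values across directed edges.

    For each directed edge i -> j, correlates the source's out-value with
    the target's in-value (degrees for ``mode='degree'``, strengths for
    ``mode='strength'``).  Returns NaN when either endpoint sample has zero
    variance (e.g. a regular graph).
    """
    sv = strengths(g)
    if mode == "degree":
        out_val, in_val = sv.k_out.astype(float), sv.k_in.astype(float)
    elif mode == "strength":
        out_val, in_val = sv.s_out, sv.s_in
    else:
        raise ValueError(f"unknown assortativity mode {mode!r}")
    src, dst = np.nonzero(g.weights)
    if len(src) < 2:
        return float("nan")
    x = out_val[src]
    y = in_val[dst]
    if x.std() == 0 or y.std() == 0:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


def clustering_coefficient(g: ConnectomeGraph) -> Tuple[np.ndarray, float]:
    """Weighted directed clustering per node (Fagiolo form) and its mean.

    With ``What`` the elementwise cube root of the max-normalized weights,

        c_i = [(What + What^T)^3]_ii / (2 * (d_i (d_i - 1) - 2 d_i^bidir))

    where ``d_i`` is total binary degree and ``d_i^bidir`` the number of
    reciprocated neighbors.  Nodes with an undefined denominator get c = 0
    and are excluded from the mean.
    """
    w = g.weights
    wmax = w.max()
    if wmax > 0:
        what = np.cbrt(w / wmax)
    else:
        what = w.copy()
    a = g.binary().astype(float)
    d_tot = (a + a.T).sum(axis=1)
    d_bidir = np.diag(a @ a)
    s = what + what.T
    numer = np.diag(s @ s @ s)
    denom = 2.0 * (d_tot * (d_tot - 1) - 2 * d_bidir)
    c = np.zeros(g.n_nodes)
    ok = denom > 0
    c[ok] = numer[ok] / denom[ok]
    mean = float(c[ok].mean()) if ok.any() else 0.0
    return c, mean


def shortest_path_matrix(L: LengthMatrix) -> np.ndarray:
    """All-pairs shortest-path lengths via Dijkstra on the length matrix."""
    finite = np.isfinite(L.lengths) & ~np.eye(L.lengths.shape[0], dtype=bool)
    graph = csr_matrix((L.lengths[finite], np.nonzero(finite)), shape=L.lengths.shape)
    return dijkstra(graph, directed=True)


def characteristic_path_length(L: LengthMatrix, mean_rule: str = "arithmetic") -> float:
    """Summary of all-pairs shortest path lengths over ordered pairs i != j.

    ``arithmetic`` averages over reachable pairs only; ``harmonic`` is the
    harmonic mean in which unreachable pairs contribute zero inverse
    distance (and therefore lengthen the summary).
    """
    d = shortest_path_matrix(L)
    n = d.shape[0]
    mask = ~np.eye(n, dtype=bool)
    vals = d[mask]
    reachable = np.isfinite(vals)
    if reachable.sum() < 2:
        raise ValueError("fewer than 2 reachable ordered pairs")
    if mean_rule == "arithmetic":
        return float(vals[reachable].mean())
    if mean_rule == "harmonic":
        inv = np.zeros_like(vals)
        pos = reachable & (vals > 0)
        inv[pos] = 1.0 / vals[pos]
        return float(len(vals) / inv.sum())
    raise ValueError(f"unknown mean_rule {mean_rule!r}")


def _null_graph(g: ConnectomeGraph, w: np.ndarray) -> ConnectomeGraph:
    return g.with_weights(w)


def small_world(
    g: ConnectomeGraph, ensemble: NullEnsemble, mean_rule: str = "arithmetic"
) -> SmallWorldIndices:
    """Null-normalized clustering and path length, and their ratio sigma.

    gamma = C / <C_null>, lambda = L / <L_null>, sigma = gamma / lambda,
    with clustering and path length computed identically on the graph and
    on every ensemble member.
    """
    _, c_emp = clustering_coefficient(g)
    l_emp = characteristic_path_length(weight_to_length(g), mean_rule)
    c_null = np.empty(ensemble.n_members)
    l_null = np.empty(ensemble.n_members)
    for i, w in enumerate(ensemble):
        gn = _null_graph(g, w)
        _, c_null[i] = clustering_coefficient(gn)
        l_null[i] = characteristic_path_length(weight_to_length(gn), mean_rule)
    if c_null.mean() == 0 or l_null.mean() == 0:
        raise ValueError("null mean is zero; indices undefined")
    gamma = c_emp / c_null.mean()
    lam = l_emp / l_null.mean()
    return SmallWorldIndices(gamma, lam, gamma / lam, c_null, l_null)


def global_metrics(g: ConnectomeGraph, mean_rule: str = "arithmetic") -> GlobalMetrics:
    """One-call bundle of the headline graph-level statistics."""
    _, c_mean = clustering_coefficient(g)
    return GlobalMetrics(
        density_directed=g.density_directed,
        density_undirected=g.density_undirected,
        reciprocity=reciprocity(g),
        assortativity_degree=assortativity(g, "degree"),
        assortativity_strength=assortativity(g, "strength"),
        clustering_mean=c_mean,
        char_path_length=characteristic_path_length(weight_to_length(g), mean_rule),
        n_nodes=g.n_nodes,
        n_edges=g.n_edges,
    )
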