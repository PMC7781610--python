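"""Multiscale community detection with consensus clustering.

Partitions maximize the directed modularity

    Q = (1/m) sum_ij [ A_ij - gamma * s_i^out s_j^in / m ] * delta(c_i, c_j)

via greedy Louvain-style optimization.  Stability across stochastic runs is
handled by Lancichinetti-Fortunato consensus clustering on the co-assignment
matrix, and scales are profiled by sweeping the resolution parameter gamma
and comparing consensus partitions with normalized mutual information.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import networkx as nx
import numpy as np

from .io import ConnectomeGraph

__all__ = [
    "ResolutionPartition",
    "ConsensusResult",
    "SweepResult",
    "modularity_score",
    "louvain_partition",
    "consensus_partition",
    "partition_nmi",
    "resolution_sweep",
]


@dataclass
class ResolutionPartition:
    """Community labels at one resolution, with their modularity."""

    resolution: float
    labels: np.ndarray
    quality: float

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)

    @property
    def n_communities(self) -> int:
        return len(np.unique(self.labels))


@dataclass
class ConsensusResult:
    partition: ResolutionPartition
    coassignment: np.ndarray
    n_runs: int
    n_iterations: int = 1


@dataclass
class SweepResult:
    gammas: np.ndarray
    results: List[ConsensusResult]
    nmi_matrix: np.ndarray
    selected_gammas: List[float] = field(default_factory=list)
    selected_indices: List[int] = field(default_factory=list)


def _canonical_labels(labels: np.ndarray) -> np.ndarray:
    """Relabel communities as contiguous integers in order of first appearance."""
    out = np.empty(len(labels), dtype=int)
    mapping: dict = {}
    for i, lab in enumerate(labels):
        if lab not in mapping:
            mapping[lab] = len(mapping)
        out[i] = mapping[lab]
    return out


def modularity_score(g: ConnectomeGraph, labels: Sequence[int], gamma: float = 1.0) -> float:
    """Directed modularity Q of a labeling at resolution gamma.

    The null term uses the product of the source's out-strength and the
    target's in-strength, normalized by total weight m.
    """
    w = g.weights
    labels = np.asarray(labels, dtype=int)
    if len(labels) != g.n_nodes:
        raise ValueError("labels length must equal node count")
    m = w.sum()
    if m <= 0:
        raise ValueError("total weight must be positive")
    s_out = w.sum(axis=1)
    s_in = w.sum(axis=0)
    q = 0.0
    for c in np.unique(labels):
        idx = labels == c
        q += w[np.ix_(idx, idx)].sum() - gamma * s_out[idx].sum() * s_in[idx].sum() / m
    return float(q / m)


def _to_digraph(w: np.ndarray) -> nx.DiGraph:
    G = nx.DiGraph()
    G.add_nodes_from(range(w.shape[0]))
    src, dst = np.nonzero(w)
    G.add_weighted_edges_from(zip(src.tolist(), dst.tolist(), w[src, dst].tolist()))
    return G


def louvain_partition(
    g: ConnectomeGraph, gamma: float = 1.0, seed: int = 0
) -> ResolutionPartition:
    """One greedy Louvain run at resolution gamma (directed modularity).

    Node sweep order is randomized by ``seed``; the same seed reproduces the
    same labels.  The returned quality is recomputed with
    :func:`modularity_score` on the final labeling.
    """
    if g.weights.sum() == 0:  # edgeless: everyone is a singleton, Q := 0
        return ResolutionPartition(gamma, np.arange(g.n_nodes), 0.0)
    G = _to_digraph(g.weights)
    comms = nx.community.louvain_communities(
        G, weight="weight", resolution=gamma, seed=int(seed)
    )
    labels = np.empty(g.n_nodes, dtype=int)
    for ci, nodes in enumerate(comms):
        for v in nodes:
            labels[v] = ci
    labels = _canonical_labels(labels)
    return ResolutionPartition(gamma, labels, modularity_score(g, labels, gamma))


def _coassignment(runs: List[np.ndarray]) -> np.ndarray:
    n = len(runs[0])
    co = np.zeros((n, n))
    for lab in runs:
        co += lab[:, None] == lab[None, :]
    co /= len(runs)
    return co


def _all_identical(runs: List[np.ndarray]) -> bool:
    first = _canonical_labels(runs[0])
    return all(np.array_equal(first, _canonical_labels(r)) for r in runs[1:])


def consensus_partition(
    g: ConnectomeGraph,
    gamma: float = 1.0,
    n_runs: int = 1000,
    tau: float = 0.4,
    seed: int = 0,
    max_iter: int = 25,
) -> ConsensusResult:
    """Lancichinetti-Fortunato consensus over stochastic Louvain runs.

    Runs Louvain ``n_runs`` times, builds the co-assignment matrix, zeroes
    entries below ``tau``, re-clusters the thresholded matrix with the same
    procedure, and iterates until all runs agree.
    """
    if n_runs < 2:
        raise ValueError("n_runs must be >= 2")
    streams = np.random.SeedSequence(seed).spawn(max_iter)

    def run_batch(graph: ConnectomeGraph, res: float, ss) -> List[np.ndarray]:
        seeds = ss.generate_state(n_runs)
        return [louvain_partition(graph, res, int(s)).labels for s in seeds]

    runs = run_batch(g, gamma, streams[0])
    co_first = _coassignment(runs)
    co = co_first
    for it in range(1, max_iter):
        if _all_identical(runs):
            labels = _canonical_labels(runs[0])
            part = ResolutionPartition(gamma, labels, modularity_score(g, labels, gamma))
            return ConsensusResult(part, co_first, n_runs, it)
        thr = np.where(co >= tau, co, 0.0)
        np.fill_diagonal(thr, 0.0)
        cg = ConnectomeGraph(thr, list(g.labels))
        # consensus matrix is symmetric; cluster it at unit resolution
        runs = run_batch(cg, 1.0, streams[it])
        co = _coassignment(runs)
    raise RuntimeError(f"consensus did not converge after {max_iter} iterations")


def partition_nmi(a: Sequence[int], b: Sequence[int]) -> float:
    """Normalized mutual information with arithmetic-mean normalization.

    Equals 1 iff the partitions are identical up to relabeling; defined as
    0 when both partitions are trivial (zero entropy).
    """
    a = np.asarray(a, dtype=int)
    b = np.asarray(b, dtype=int)
    if a.shape != b.shape:
        raise ValueError("label vectors must have equal length")
    n = len(a)
    ua, ia = np.unique(a, return_inverse=True)
    ub, ib = np.unique(b, return_inverse=True)
    cont = np.zeros((len(ua), len(ub)))
    np.add.at(cont, (ia, ib), 1.0)
    p = cont / n
    pa = p.sum(axis=1)
    pb = p.sum(axis=0)
    ha = -np.sum(pa * np.log(pa, where=pa > 0, out=np.zeros_like(pa)))
    hb = -np.sum(pb * np.log(pb, where=pb > 0, out=np.zeros_like(pb)))
    if ha == 0 and hb == 0:
        return 0.0
    outer = pa[:, None] * pb[None, :]
    nz = p > 0
    mi = np.sum(p[nz] * np.log(p[nz] / outer[nz]))
    denom = (ha + hb) / 2.0
    if denom == 0:
        return 0.0
    return float(np.clip(mi / denom, 0.0, 1.0))


def _select_scales(
    gammas: np.ndarray, nmi: np.ndarray, min_width: float = 0.2, pct: float = 90.0
):
    """Plateau detection on the cross-resolution NMI matrix.

    A scale is a maximal contiguous run of grid points whose mean pairwise
    NMI (within the run) exceeds the given percentile of all off-diagonal
    NMI values, spanning a gamma width larger than ``min_width``.  The
    center index of each qualifying run is reported.
    """
    k = len(gammas)
    if k == 1:
        return [0]
    off = nmi[~np.eye(k, dtype=bool)]
    thresh = np.percentile(off, pct)
    # per-point score: mean NMI with neighbors within the sweep
    selected: List[int] = []
    i = 0
    while i < k:
        j = i
        while j + 1 < k and nmi[j, j + 1] >= thresh:
            j += 1
        if j > i:
            block = nmi[i : j + 1, i : j + 1]
            mean_block = block[~np.eye(j - i + 1, dtype=bool)].mean()
            if gammas[j] - gammas[i] > min_width and mean_block >= thresh:
                selected.append((i + j) // 2)
        i = j + 1
    return selected


def resolution_sweep(
    g: ConnectomeGraph,
    gamma_grid: Sequence[float],
    n_runs: int = 1000,
    tau: float = 0.4,
    seed: int = 0,
) -> SweepResult:
    """Consensus partitions over a resolution grid plus an NMI scale profile."""
    gammas = np.asarray(sorted(gamma_grid), dtype=float)
    if gammas.size == 0:
        raise ValueError("empty resolution grid")
    if np.any(gammas <= 0):
        raise ValueError("resolutions must be positive")
    streams = np.random.SeedSequence(seed).spawn(len(gammas))
    results = [
        consensus_partition(g, float(gam), n_runs, tau, int(ss.generate_state(1)[0]))
        for gam, ss in zip(gammas, streams)
    ]
    k = len(gammas)
    nmi = np.eye(k)
    for i in range(k):
        for j in range(i + 1, k):
            nmi[i, j] = nmi[j, i] = partition_nmi(
                results[i].partition.labels, results[j].partition.labels
            )
    idx = _select_scales(gammas, nmi) if k > 1 else [0]
    return SweepResult(gammas, results, nmi, [float(gammas[i]) for i in idx], idx)
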