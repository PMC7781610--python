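"""Persistent homology of weighted networks via clique-complex edge filtration.

Edges enter one at a time in order of decreasing (symmetrized) weight; a
clique enters the complex as soon as its last edge does (flag complex, up
to tetrahedra).  Homology is computed over the 2-element field by standard
boundary-matrix column reduction, yielding persistence bars for components
(H0), 2D holes (H1) and 3D voids (H2) with representative cycles.

Each simplex carries two filtration scales: the integer rank of its latest
edge (1-based position in the sorted edge list; vertices have rank 0) and
the metric value -ln(w / w_max) of that edge.  Null comparisons use ranks
so that ensembles with different weight ranges stay comparable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .io import ConnectomeGraph, symmetrize
from .nulls import NullEnsemble, empirical_pvalue

__all__ = [
    "Filtration",
    "PersistenceBar",
    "PersistenceDiagram",
    "build_filtration",
    "persistent_homology",
    "cavity_significance",
]


@dataclass(frozen=True)
class FiltSimplex:
    vertices: Tuple[int, ...]
    rank: int  # 1-based rank of the latest edge; 0 for vertices
    value: float  # -ln(w / w_max) of the latest edge; 0 for vertices

    @property
    def dim(self) -> int:
        return len(self.vertices) - 1


@dataclass
class Filtration:
    simplices: List[FiltSimplex]
    labels: Sequence[str]
    n_edges: int  # number of undirected edges in the filtration
    max_dim: int = 3  # largest simplex dimension requested (homology valid to max_dim - 1)

    def __len__(self) -> int:
        return len(self.simplices)


@dataclass
class PersistenceBar:
    dimension: int
    birth_rank: int
    death_rank: float  # inf for immortal bars
    birth_value: float
    death_value: float
    representative: List[Tuple[int, ...]]  # simplices of the cycle

    @property
    def lifetime(self) -> float:
        """Lifetime on the rank scale (inf for immortal bars)."""
        return self.death_rank - self.birth_rank

    @property
    def immortal(self) -> bool:
        return np.isinf(self.death_rank)


@dataclass
class PersistenceDiagram:
    bars: List[PersistenceBar]
    max_dim: int
    n_edges: int

    def bars_in_dim(self, dim: int, include_zero_length: bool = False):
        out = [b for b in self.bars if b.dimension == dim]
        if not include_zero_length:
            out = [b for b in out if b.lifetime > 0]
        return out

    def betti(self) -> Tuple[int, ...]:
        """Final Betti numbers (beta_0, ..., beta_maxhom) of the full complex."""
        top = self.max_dim - 1
        return tuple(
            sum(1 for b in self.bars if b.dimension == d and b.immortal)
            for d in range(top + 1)
        )


def build_filtration(
    g: ConnectomeGraph, symmetrize_rule: str = "max", max_dim: int = 3
) -> Filtration:
    """Decreasing-weight edge filtration of the clique complex of ``g``.

    The directed graph is symmetrized (``max`` or ``mean``), undirected
    edges are sorted by strictly decreasing weight (ties broken by
    lexicographic endpoints, so repeated runs are identical), and every
    simplex receives the rank and value of its latest edge.  ``max_dim`` is
    the largest simplex dimension (3 = tetrahedra, enough for H2).
    """
    if max_dim > 3:
        raise ValueError("max_dim must be <= 3")
    if max_dim < 1:
        raise ValueError("max_dim must be >= 1")
    if symmetrize_rule not in ("max", "mean"):
        raise ValueError("symmetrize_rule must be 'max' or 'mean'")
    sym = symmetrize(g, symmetrize_rule).weights
    n = g.n_nodes
    iu, ju = np.triu_indices(n, 1)
    present = sym[iu, ju] > 0
    edges = list(zip(sym[iu, ju][present], iu[present], ju[present]))
    edges.sort(key=lambda e: (-e[0], e[1], e[2]))
    wmax = edges[0][0] if edges else 1.0

    simplices: List[FiltSimplex] = [FiltSimplex((v,), 0, 0.0) for v in range(n)]
    adj: List[set] = [set() for _ in range(n)]
    for rank, (w, u, v) in enumerate(edges, start=1):
        value = float(max(0.0, -np.log(w / wmax)))
        simplices.append(FiltSimplex((u, v), rank, value))
        if max_dim >= 2:
            common = sorted(adj[u] & adj[v])
            for x in common:
                simplices.append(FiltSimplex(tuple(sorted((u, v, x))), rank, value))
            if max_dim >= 3:
                for a, b in combinations(common, 2):
                    if b in adj[a]:
                        simplices.append(
                            FiltSimplex(tuple(sorted((u, v, a, b))), rank, value)
                        )
        adj[u].add(v)
        adj[v].add(u)
    return Filtration(simplices, list(g.labels), len(edges), max_dim)


def persistent_homology(f: Filtration) -> PersistenceDiagram:
    """Persistence bars of a filtration by GF(2) boundary-matrix reduction.

    Columns are stored as Python integer bitsets.  A simplex whose reduced
    boundary vanishes creates a class; a simplex whose reduced boundary has
    pivot i kills the class created by simplex i, producing a bar whose
    representative cycle is the reduced boundary column at pairing time.
    Immortal bars take their representative from the reduction's
    accumulated column combination.
    """
    index_of: Dict[Tuple[int, ...], int] = {}
    for idx, s in enumerate(f.simplices):
        if s.vertices in index_of:
            raise ValueError(f"duplicate simplex {s.vertices}")
        index_of[s.vertices] = idx

    n_simp = len(f.simplices)
    pivot_of_row: Dict[int, int] = {}
    stored_r: Dict[int, int] = {}
    stored_v: Dict[int, int] = {}
    creator = [False] * n_simp
    killed_by: Dict[int, int] = {}
    rep_of_death: Dict[int, int] = {}

    for j, s in enumerate(f.simplices):
        col = 0
        if s.dim > 0:
            for face in combinations(s.vertices, s.dim):
                fi = index_of.get(face)
                if fi is None or fi > j:
                    raise ValueError(f"face {face} missing or out of order")
                col |= 1 << fi
        vcol = 1 << j
        while col:
            low = col.bit_length() - 1
            piv = pivot_of_row.get(low)
            if piv is None:
                break
            col ^= stored_r[piv]
            vcol ^= stored_v[piv]
        if col == 0:
            creator[j] = True
            stored_v[j] = vcol
        else:
            low = col.bit_length() - 1
            pivot_of_row[low] = j
            stored_r[j] = col
            stored_v[j] = vcol
            killed_by[low] = j
            rep_of_death[j] = col

    def _support(bits: int) -> List[int]:
        out = []
        while bits:
            low = bits & -bits
            out.append(low.bit_length() - 1)
            bits ^= low
        return out

    bars: List[PersistenceBar] = []
    # homology is only valid up to one below the truncation dimension
    top_hom = f.max_dim - 1
    for i, s in enumerate(f.simplices):
        if not creator[i]:
            continue
        if i in killed_by:
            j = killed_by[i]
            d = f.simplices[j]
            rep = [f.simplices[k].vertices for k in _support(rep_of_death[j])]
            bars.append(
                PersistenceBar(s.dim, s.rank, float(d.rank), s.value, d.value, rep)
            )
        elif s.dim <= top_hom:
            rep = [f.simplices[k].vertices for k in _support(stored_v[i])]
            bars.append(
                PersistenceBar(s.dim, s.rank, float("inf"), s.value, float("inf"), rep)
            )
    return PersistenceDiagram(bars, f.max_dim, f.n_edges)


@dataclass
class CavityDimReport:
    dimension: int
    n_bars: int
    lifetime_threshold: float
    n_long_bars: int
    p_count: float
    p_longest: float
    longest_lifetime: float
    null_n_long: np.ndarray
    null_longest: np.ndarray
    lifetime_quantiles: Tuple[float, float, float]
    top_bars: List[dict] = field(default_factory=list)


def _finite_lifetimes(diag: PersistenceDiagram, dim: int, cap: float) -> np.ndarray:
    out = []
    for b in diag.bars_in_dim(dim):
        death = min(b.death_rank, cap)
        out.append(death - b.birth_rank)
    return np.asarray(out, dtype=float)


def cavity_significance(
    g: ConnectomeGraph,
    ensemble: NullEnsemble,
    top_m: int = 5,
    dims: Sequence[int] = (1, 2),
    symmetrize_rule: str = "max",
    max_dim: int = 3,
    lifetime_threshold: Optional[float] = None,
) -> Dict[int, CavityDimReport]:
    """Compare cavity lifetimes of ``g`` against its rewired null ensemble.

    Lifetimes are measured on the rank scale, with immortal bars capped at
    one past the final edge rank.  Per dimension, two empirical p-values
    are reported: for the number of bars whose lifetime exceeds a threshold
    (default: the median lifetime pooled over the null bars of that
    dimension) and for the single longest lifetime.  The ``top_m`` empirical
    bars per dimension are returned with representative cycles mapped to
    node labels.
    """
    diag = persistent_homology(build_filtration(g, symmetrize_rule, max_dim))
    cap = diag.n_edges + 1.0
    null_diags = []
    for w in ensemble:
        if w.shape != g.weights.shape:
            raise ValueError("ensemble members do not match graph size")
        gn = g.with_weights(w)
        null_diags.append(persistent_homology(build_filtration(gn, symmetrize_rule, max_dim)))

    reports: Dict[int, CavityDimReport] = {}
    for dim in dims:
        life = _finite_lifetimes(diag, dim, cap)
        null_lives = [_finite_lifetimes(nd, dim, min(nd.n_edges + 1.0, cap)) for nd in null_diags]
        pooled = np.concatenate([nl for nl in null_lives if nl.size]) if null_lives else np.array([])
        if lifetime_threshold is None:
            thr = float(np.median(pooled)) if pooled.size else 0.0
        else:
            thr = float(lifetime_threshold)
        n_long = int(np.sum(life > thr))
        null_n_long = np.array([np.sum(nl > thr) for nl in null_lives], dtype=float)
        longest = float(life.max()) if life.size else 0.0
        null_longest = np.array([nl.max() if nl.size else 0.0 for nl in null_lives])
        quantiles = (
            tuple(np.percentile(life, [25, 50, 75])) if life.size else (0.0, 0.0, 0.0)
        )
        bars = sorted(
            diag.bars_in_dim(dim),
            key=lambda b: min(b.death_rank, cap) - b.birth_rank,
            reverse=True,
        )[:top_m]
        top = [
            {
                "dimension": dim,
                "birth_rank": b.birth_rank,
                "death_rank": b.death_rank,
                "birth_value": b.birth_value,
                "death_value": b.death_value,
                "lifetime_rank": min(b.death_rank, cap) - b.birth_rank,
                "nodes": sorted(
                    {g.labels[v] for simplex in b.representative for v in simplex}
                ),
            }
            for b in bars
        ]
        reports[dim] = CavityDimReport(
            dimension=dim,
            n_bars=int(life.size),
            lifetime_threshold=thr,
            n_long_bars=n_long,
            p_count=empirical_pvalue(n_long, null_n_long, "greater"),
            p_longest=empirical_pvalue(longest, null_longest, "greater"),
            longest_lifetime=longest,
            null_n_long=null_n_long,
            null_longest=null_longest,
            lifetime_quantiles=quantiles,
            top_bars=top,
        )
    return reports
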