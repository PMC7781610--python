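"""Three-node motif census and rewired-null significance spectrum.

Motif classes are isomorphism classes of weakly connected simple digraphs
on unlabeled nodes; for 3 nodes there are 13 of them.  Class identities
1..13 follow the Brain Connectivity Toolbox convention, reconstructed
algorithmically here: each class is labeled by its sorted multiset of
(out-degree, in-degree) pairs (which separates all 13 classes on 3 nodes),
and IDs are assigned by the lexicographic order of those labels with all
out-degrees preceding all in-degrees.  Under this ordering class 9 is the
reciprocal chain a<->b<->c and class 13 the fully reciprocal triangle.

Counting is induced by default (each connected unordered triple counted
once, in the class of its full induced subgraph); a partial (subgraph)
census is available behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations, permutations
from typing import Dict, List, Tuple

import numpy as np

from .io import ConnectomeGraph
from .nulls import NullEnsemble, empirical_pvalue

__all__ = [
    "MotifSpectrum",
    "motif_class_count",
    "motif3_census",
    "motif_significance",
    "MOTIF3_REPRESENTATIVES",
    "N_MOTIF3_CLASSES",
]

N_MOTIF3_CLASSES = 13

# ordered off-diagonal entries used to encode an n-node digraph as bits
def _pair_order(n: int) -> List[Tuple[int, int]]:
    return [(i, j) for i in range(n) for j in range(n) if i != j]


def _bits_to_matrix(bits: int, n: int) -> np.ndarray:
    a = np.zeros((n, n), dtype=int)
    for idx, (i, j) in enumerate(_pair_order(n)):
        if (bits >> idx) & 1:
            a[i, j] = 1
    return a


def _matrix_to_bits(a: np.ndarray) -> int:
    bits = 0
    for idx, (i, j) in enumerate(_pair_order(a.shape[0])):
        if a[i, j]:
            bits |= 1 << idx
    return bits


def _weakly_connected(a: np.ndarray) -> bool:
    n = a.shape[0]
    und = (a + a.T) > 0
    seen = {0}
    stack = [0]
    while stack:
        v = stack.pop()
        for u in range(n):
            if und[v, u] and u not in seen:
                seen.add(u)
                stack.append(u)
    return len(seen) == n


def _canonical_form(a: np.ndarray) -> int:
    """Minimum bit encoding over all vertex permutations."""
    n = a.shape[0]
    best = None
    for perm in permutations(range(n)):
        p = list(perm)
        b = _matrix_to_bits(a[np.ix_(p, p)])
        if best is None or b < best:
            best = b
    return best


def motif_class_count(n: int) -> int:
    """Number of isomorphism classes of weakly connected simple digraphs on n nodes.

    Computed by exhaustive enumeration of all 2^(n(n-1)) labeled digraphs,
    filtering to weakly connected ones and collapsing under the n! vertex
    permutations.  Supports n in {2, 3, 4} (3 -> 13 classes, 4 -> 199).
    """
    if n not in (2, 3, 4):
        raise ValueError("motif_class_count supports n in {2, 3, 4}")
    classes = set()
    for bits in range(1 << (n * (n - 1))):
        a = _bits_to_matrix(bits, n)
        if _weakly_connected(a):
            classes.add(_canonical_form(a))
    return len(classes)


def _degree_pair_label(a: np.ndarray) -> Tuple[int, ...]:
    """Sorted (out, in) degree pairs, flattened out-degrees first."""
    pairs = sorted(zip(a.sum(axis=1).tolist(), a.sum(axis=0).tolist()))
    return tuple(p[0] for p in pairs) + tuple(p[1] for p in pairs)


def _build_motif3_tables():
    """Class representatives in canonical ID order plus a 64-entry lookup.

    Returns (representatives, lookup) where lookup[bits] is the 1-based
    class ID of the 3-node pattern encoded by ``bits`` (0 if not weakly
    connected).
    """
    by_label: Dict[Tuple[int, ...], List[int]] = {}
    canon_of_bits = {}
    for bits in range(64):
        a = _bits_to_matrix(bits, 3)
        if not _weakly_connected(a):
            continue
        label = _degree_pair_label(a)
        by_label.setdefault(label, []).append(bits)
    # degree-pair labels separate all 13 classes on 3 nodes; assert anyway
    assert len(by_label) == N_MOTIF3_CLASSES
    ordered_labels = sorted(by_label)
    reps = []
    lookup = np.zeros(64, dtype=int)
    for cid, label in enumerate(ordered_labels, start=1):
        members = by_label[label]
        canon = min(_canonical_form(_bits_to_matrix(b, 3)) for b in members)
        reps.append(_bits_to_matrix(canon, 3))
        for b in members:
            lookup[b] = cid
    return reps, lookup


MOTIF3_REPRESENTATIVES, _MOTIF3_LOOKUP = _build_motif3_tables()

# partial-census table: row per 64-bit pattern, column per class; entry =
# number of weakly connected edge subsets of the pattern in that class
def _build_partial_table() -> np.ndarray:
    table = np.zeros((64, N_MOTIF3_CLASSES), dtype=np.int64)
    for bits in range(64):
        sub = bits
        while True:  # iterate over all subsets of the set bits
            cid = _MOTIF3_LOOKUP[sub]
            if cid:
                table[bits, cid - 1] += 1
            if sub == 0:
                break
            sub = (sub - 1) & bits
    return table


_MOTIF3_PARTIAL = _build_partial_table()


@dataclass
class MotifSpectrum:
    """Per-class occurrence counts, with null distributions when available."""

    class_count: np.ndarray  # (13,)
    null_counts: np.ndarray = None  # (13, n_members)
    p_two_tailed: np.ndarray = None
    direction: List[str] = None  # per class: enriched | depleted | ns

    @property
    def n_connected_triples(self) -> int:
        return int(self.class_count.sum())


def _triple_patterns(adj: np.ndarray) -> np.ndarray:
    """Bit pattern of the induced subgraph for every unordered node triple."""
    n = adj.shape[0]
    triples = np.array(list(combinations(range(n), 3)))
    i, j, k = triples[:, 0], triples[:, 1], triples[:, 2]
    # pair order for nodes (0,1,2): (0,1),(0,2),(1,0),(1,2),(2,0),(2,1)
    bits = (
        adj[i, j] * 1
        + adj[i, k] * 2
        + adj[j, i] * 4
        + adj[j, k] * 8
        + adj[k, i] * 16
        + adj[k, j] * 32
    )
    return bits


def _census_from_adj(adj: np.ndarray, induced: bool) -> np.ndarray:
    bits = _triple_patterns(adj)
    if induced:
        ids = _MOTIF3_LOOKUP[bits]
        counts = np.bincount(ids, minlength=N_MOTIF3_CLASSES + 1)[1:]
        return counts.astype(np.int64)
    return _MOTIF3_PARTIAL[bits].sum(axis=0)


def motif3_census(g: ConnectomeGraph, induced: bool = True) -> MotifSpectrum:
    """Occurrence count of each of the 13 three-node motif classes.

    With ``induced=True`` (default) each weakly connected unordered triple
    contributes one occurrence, classified by its full induced subgraph.
    With ``induced=False`` every weakly connected edge subset of every
    triple is counted (partial/subgraph census).
    """
    if g.n_nodes < 3:
        raise ValueError("need at least 3 nodes")
    return MotifSpectrum(_census_from_adj(g.binary(), induced))


def motif_significance(
    g: ConnectomeGraph, ensemble: NullEnsemble, induced: bool = True
) -> MotifSpectrum:
    """Motif spectrum of ``g`` with two-tailed empirical p-values vs nulls.

    Direction is 'enriched' (p <= 0.05 and count above the null median),
    'depleted' (below), or 'ns'.
    """
    counts = _census_from_adj(g.binary(), induced)
    null_counts = np.empty((N_MOTIF3_CLASSES, ensemble.n_members), dtype=np.int64)
    for j, w in enumerate(ensemble):
        if w.shape != g.weights.shape:
            raise ValueError("ensemble members do not match graph size")
        null_counts[:, j] = _census_from_adj((w > 0).astype(int), induced)
    p = np.array(
        [empirical_pvalue(counts[c], null_counts[c], tail="two") for c in range(N_MOTIF3_CLASSES)]
    )
    med = np.median(null_counts, axis=1)
    direction = [
        "ns" if p[c] > 0.05 else ("enriched" if counts[c] > med[c] else "depleted")
        for c in range(N_MOTIF3_CLASSES)
    ]
    return MotifSpectrum(counts, null_counts, p, direction)
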