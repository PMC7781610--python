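"""Hub detection: participation coefficients, source/sink ratios, rich club.

The participation coefficient measures how evenly a node's afferent or
efferent strength is spread over communities (0 = all within one module,
approaching 1 - 1/C for an even split over C modules).  The rich-club
curve phi(k) is the directed binary density of the subgraph of nodes whose
total degree exceeds k, compared per k against a degree-preserving rewired
null ensemble.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.stats import rankdata

from .io import ConnectomeGraph
from .global_topology import strengths
from .nulls import NullEnsemble, empirical_pvalue

__all__ = [
    "ParticipationProfile",
    "RichClubCurve",
    "participation",
    "participation_rank_profile",
    "strength_ratio",
    "rich_club",
]


@dataclass
class ParticipationProfile:
    p_in: np.ndarray
    p_out: np.ndarray
    zero_in: np.ndarray  # nodes with zero in-strength (participation set to 0)
    zero_out: np.ndarray


@dataclass
class RichClubCurve:
    k_levels: np.ndarray
    phi: np.ndarray
    phi_rand: np.ndarray  # (n_levels, n_members); NaN where undefined
    phi_norm: np.ndarray
    p_values: np.ndarray
    survivors: np.ndarray  # surviving-node count per level

    @property
    def significant_regime(self) -> Optional[Tuple[int, int]]:
        """Maximal contiguous k range with p <= 0.05 and phi_norm > 1."""
        ok = (self.p_values <= 0.05) & (self.phi_norm > 1)
        best = None
        i = 0
        while i < len(ok):
            if ok[i]:
                j = i
                while j + 1 < len(ok) and ok[j + 1]:
                    j += 1
                if best is None or (j - i) > (best[1] - best[0]):
                    best = (i, j)
                i = j + 1
            else:
                i += 1
        if best is None:
            return None
        return int(self.k_levels[best[0]]), int(self.k_levels[best[1]])


def participation(g: ConnectomeGraph, labels: Sequence[int]) -> ParticipationProfile:
    """In/out participation coefficients for one partition.

    p_i = 1 - sum_c (s_i(c) / s_i)^2, where s_i(c) is node i's strength
    restricted to community c.  Nodes with zero total strength in a
    direction get participation 0 and are flagged.
    """
    labels = np.asarray(labels, dtype=int)
    if len(labels) != g.n_nodes:
        raise ValueError("labels length must equal node count")
    w = g.weights
    comms = np.unique(labels)
    onehot = (labels[:, None] == comms[None, :]).astype(float)  # n x C
    s_in_c = w.T @ onehot  # afferent strength per community
    s_out_c = w @ onehot
    s_in = s_in_c.sum(axis=1)
    s_out = s_out_c.sum(axis=1)

    def _p(per_comm, total):
        zero = total == 0
        safe = np.where(zero, 1.0, total)
        p = 1.0 - ((per_comm / safe[:, None]) ** 2).sum(axis=1)
        p[zero] = 0.0
        return p, zero

    p_in, zi = _p(s_in_c, s_in)
    p_out, zo = _p(s_out_c, s_out)
    return ParticipationProfile(p_in, p_out, zi, zo)


def participation_rank_profile(
    g: ConnectomeGraph, partitions: Sequence[Sequence[int]]
) -> Tuple[np.ndarray, np.ndarray]:
    """Mean participation ranks across partitions (in, out).

    Within each partition nodes are ranked by participation (ties get the
    average rank, highest participation = highest rank), then ranks are
    averaged across partitions.  Invariant to monotone transforms of the
    participation values.
    """
    if len(partitions) == 0:
        raise ValueError("need at least one partition")
    ranks_in = np.zeros(g.n_nodes)
    ranks_out = np.zeros(g.n_nodes)
    for labels in partitions:
        prof = participation(g, labels)
        ranks_in += rankdata(prof.p_in)
        ranks_out += rankdata(prof.p_out)
    return ranks_in / len(partitions), ranks_out / len(partitions)


def strength_ratio(g: ConnectomeGraph, log_ratio: bool = False):
    """Out/in strength ratio per node and its correlation with total strength.

    Nodes with zero in-strength have an undefined ratio; they are flagged
    (NaN) and excluded from the correlation.  ``log_ratio=True`` correlates
    ln(ratio) instead (more robust to skew); the default is the raw ratio.

    Returns
    -------
    ratio : ndarray
    total : ndarray
    corr : float (NaN if undefined)
    valid : boolean ndarray
    """
    sv = strengths(g)
    valid = sv.s_in > 0
    ratio = np.full(g.n_nodes, np.nan)
    ratio[valid] = sv.s_out[valid] / sv.s_in[valid]
    total = sv.total_strength
    x = ratio[valid]
    if log_ratio:
        pos = x > 0
        x = np.log(x[pos])
        y = total[valid][pos]
    else:
        y = total[valid]
    if len(x) < 2 or np.std(x) == 0 or np.std(y) == 0:
        corr = float("nan")
    else:
        corr = float(np.corrcoef(y, x)[0, 1])
    return ratio, total, corr, valid


def _phi(adj: np.ndarray, degree: np.ndarray, k: int, keep_geq: bool) -> Tuple[float, int]:
    keep = degree >= k if keep_geq else degree > k
    m = int(keep.sum())
    if m < 2:
        return float("nan"), m
    sub = adj[np.ix_(keep, keep)]
    return float(sub.sum() / (m * (m - 1))), m


def rich_club(
    g: ConnectomeGraph, ensemble: NullEnsemble, keep_geq: bool = False
) -> RichClubCurve:
    """Rich-club curve with null distribution and per-k empirical p-values.

    At each degree level k, nodes with total binary degree <= k are removed
    (``keep_geq=True`` flips to removing degree < k) and phi(k) is the
    directed binary density of the surviving subgraph.  The identical
    procedure runs on every null member; the p-value per k is the
    proportion of null coefficients at least as large as the empirical one.
    """
    adj = g.binary()
    degree = adj.sum(axis=0) + adj.sum(axis=1)
    for w in ensemble:
        if w.shape != g.weights.shape:
            raise ValueError("ensemble members do not match graph size")
    k_levels = np.arange(0, int(degree.max()))
    phi = np.empty(len(k_levels))
    survivors = np.empty(len(k_levels), dtype=int)
    for i, k in enumerate(k_levels):
        phi[i], survivors[i] = _phi(adj, degree, int(k), keep_geq)

    phi_rand = np.full((len(k_levels), ensemble.n_members), np.nan)
    for j, w in enumerate(ensemble):
        a = (w > 0).astype(int)
        d = a.sum(axis=0) + a.sum(axis=1)
        for i, k in enumerate(k_levels):
            phi_rand[i, j], _ = _phi(a, d, int(k), keep_geq)

    defined = ~np.isnan(phi)
    phi_norm = np.full(len(k_levels), np.nan)
    p_values = np.full(len(k_levels), np.nan)
    for i in np.nonzero(defined)[0]:
        nulls = phi_rand[i][~np.isnan(phi_rand[i])]
        if nulls.size == 0:
            continue
        mean_null = nulls.mean()
        if mean_null > 0:
            phi_norm[i] = phi[i] / mean_null
        p_values[i] = empirical_pvalue(phi[i], nulls, tail="greater")
    keep = defined
    return RichClubCurve(
        k_levels[keep], phi[keep], phi_rand[keep], phi_norm[keep], p_values[keep], survivors[keep]
    )
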