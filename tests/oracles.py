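"""Independent brute-force oracles used to cross-check the package.

Everything here is deliberately written as plain loops / direct linear
algebra, sharing no code path with the implementation under test.
"""

from itertools import combinations, permutations

import numpy as np


def distances_bruteforce(coords):
    n = len(coords)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            d[i, j] = np.sqrt(sum((coords[i, k] - coords[j, k]) ** 2 for k in range(3)))
    return d


def reciprocity_bruteforce(w):
    """Direct double-sum evaluation of the matrix/transpose correlation."""
    n = w.shape[0]
    vals = [w[i, j] for i in range(n) for j in range(n) if i != j]
    wbar = sum(vals) / len(vals)
    num = sum(
        (w[i, j] - wbar) * (w[j, i] - wbar) for i in range(n) for j in range(n) if i != j
    )
    den = sum((w[i, j] - wbar) ** 2 for i in range(n) for j in range(n) if i != j)
    return num / den


def assortativity_bruteforce(w, mode="degree"):
    """Edge-list Pearson correlation of (source out-value, target in-value)."""
    n = w.shape[0]
    a = (w > 0).astype(float)
    if mode == "degree":
        out_val = a.sum(axis=1)
        in_val = a.sum(axis=0)
    else:
        out_val = w.sum(axis=1)
        in_val = w.sum(axis=0)
    xs, ys = [], []
    for i in range(n):
        for j in range(n):
            if w[i, j] > 0:
                xs.append(out_val[i])
                ys.append(in_val[j])
    xs, ys = np.array(xs), np.array(ys)
    return float(np.corrcoef(xs, ys)[0, 1])


def fagiolo_clustering_bruteforce(w):
    """Per-node weighted directed clustering via explicit triple enumeration."""
    n = w.shape[0]
    wmax = w.max()
    what = (w / wmax) ** (1.0 / 3.0) if wmax > 0 else w * 0.0
    a = (w > 0).astype(int)
    c = np.zeros(n)
    for i in range(n):
        num = 0.0
        for j in range(n):
            for k in range(n):
                s_ij = what[i, j] + what[j, i]
                s_jk = what[j, k] + what[k, j]
                s_ki = what[k, i] + what[i, k]
                num += s_ij * s_jk * s_ki
        d_tot = sum(a[i, j] + a[j, i] for j in range(n))
        d_bi = sum(a[i, j] * a[j, i] for j in range(n))
        den = 2.0 * (d_tot * (d_tot - 1) - 2 * d_bi)
        c[i] = num / den if den > 0 else 0.0
    return c


def participation_bruteforce(w, labels):
    """Per-community strength accumulation with explicit loops."""
    n = w.shape[0]
    comms = sorted(set(labels))
    p_in = np.zeros(n)
    p_out = np.zeros(n)
    for i in range(n):
        s_in = sum(w[j, i] for j in range(n))
        s_out = sum(w[i, j] for j in range(n))
        if s_in > 0:
            p_in[i] = 1.0 - sum(
                (sum(w[j, i] for j in range(n) if labels[j] == c) / s_in) ** 2
                for c in comms
            )
        if s_out > 0:
            p_out[i] = 1.0 - sum(
                (sum(w[i, j] for j in range(n) if labels[j] == c) / s_out) ** 2
                for c in comms
            )
    return p_in, p_out


def rich_club_phi_bruteforce(w, k, keep_geq=False):
    """Explicit node filter + edge count."""
    a = (w > 0).astype(int)
    n = a.shape[0]
    deg = [sum(a[i, j] + a[j, i] for j in range(n)) for i in range(n)]
    keep = [i for i in range(n) if (deg[i] >= k if keep_geq else deg[i] > k)]
    m = len(keep)
    if m < 2:
        return None
    edges = sum(a[i, j] for i in keep for j in keep)
    return edges / (m * (m - 1))


def motif3_census_bruteforce(adj, representatives):
    """Induced-triad census classifying by trying all 6 vertex permutations."""
    n = adj.shape[0]
    counts = np.zeros(len(representatives), dtype=int)
    for trip in combinations(range(n), 3):
        sub = adj[np.ix_(trip, trip)]
        und = (sub + sub.T) > 0
        # weak connectivity on 3 nodes: every vertex touched and not split
        reach = {0}
        frontier = [0]
        while frontier:
            v = frontier.pop()
            for u in range(3):
                if und[v, u] and u not in reach:
                    reach.add(u)
                    frontier.append(u)
        if len(reach) != 3:
            continue
        for cid, rep in enumerate(representatives):
            if any(
                np.array_equal(sub[np.ix_(p, p)], rep)
                for p in permutations(range(3))
            ):
                counts[cid] += 1
                break
        else:
            raise AssertionError("triad matched no representative")
    return counts


def count_connected_triples(adj):
    """Connectivity-only counter of weakly connected induced triples."""
    n = adj.shape[0]
    und = (adj + adj.T) > 0
    total = 0
    for i, j, k in combinations(range(n), 3):
        e = [und[i, j], und[j, k], und[i, k]]
        if sum(e) >= 2:
            total += 1
    return total


def gf2_rank(mat):
    """Rank of a 0/1 matrix over GF(2) by Gaussian elimination."""
    m = [int("".join(str(int(x)) for x in row), 2) if len(row) else 0 for row in mat]
    rank = 0
    for col in range(mat.shape[1] if mat.size else 0):
        bit = 1 << (mat.shape[1] - 1 - col)
        piv = None
        for r in range(rank, len(m)):
            if m[r] & bit:
                piv = r
                break
        if piv is None:
            continue
        m[rank], m[piv] = m[piv], m[rank]
        for r in range(len(m)):
            if r != rank and m[r] & bit:
                m[r] ^= m[rank]
        rank += 1
    return rank


def betti_numbers_bruteforce(simplices, max_hom_dim=3):
    """Betti numbers of a simplicial complex from boundary-matrix ranks.

    ``simplices`` is an iterable of vertex tuples (all faces included).
    beta_d = dim C_d - rank d_d - rank d_{d+1}.
    """
    by_dim = {}
    for s in simplices:
        by_dim.setdefault(len(s) - 1, []).append(tuple(sorted(s)))
    for d in by_dim:
        by_dim[d] = sorted(set(by_dim[d]))
    max_d = max(by_dim) if by_dim else 0
    ranks = {}
    for d in range(1, max_d + 1):
        rows = by_dim.get(d - 1, [])
        cols = by_dim.get(d, [])
        row_idx = {s: i for i, s in enumerate(rows)}
        mat = np.zeros((len(rows), len(cols)), dtype=int)
        for cj, s in enumerate(cols):
            for face in combinations(s, d):
                mat[row_idx[tuple(sorted(face))], cj] = 1
        ranks[d] = gf2_rank(mat) if mat.size else 0
    betti = []
    for d in range(0, min(max_hom_dim, max_d) + 1):
        n_d = len(by_dim.get(d, []))
        betti.append(n_d - ranks.get(d, 0) - ranks.get(d + 1, 0))
    return tuple(betti)


def h0_count_union_find(n, edges_in_order, upto):
    """Number of connected components after the first ``upto`` edges."""
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for u, v in edges_in_order[:upto]:
        ru, rv = find(u), find(v)
        if ru != rv:
            parent[ru] = rv
    return len({find(i) for i in range(n)})
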