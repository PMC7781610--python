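import numpy as np
import pytest

from connectocore import (
    ConnectomeGraph,
    build_ensemble,
    build_filtration,
    cavity_significance,
    fixture_graph,
    persistent_homology,
)

from conftest import random_digraph
from oracles import betti_numbers_bruteforce, h0_count_union_find


def betti_at_rank(diag, rank, dim):
    """Betti number after all simplices of edge rank <= rank entered."""
    return sum(
        1
        for b in diag.bars
        if b.dimension == dim and b.birth_rank <= rank and rank < b.death_rank
    )


class TestFiltration:
    def test_edges_in_decreasing_weight_order(self):
        w = np.zeros((3, 3))
        w[0, 1] = 0.9
        w[1, 2] = 0.5
        w[0, 2] = 0.1
        g = ConnectomeGraph(w, list("ABC"))
        f = build_filtration(g)
        edges = [s for s in f.simplices if s.dim == 1]
        assert [s.rank for s in edges] == [1, 2, 3]
        assert edges[0].vertices == (0, 1)
        assert edges[1].vertices == (1, 2)
        assert edges[2].vertices == (0, 2)
        assert edges[0].value == 0.0  # max weight -> length 0

    def test_triangle_enters_with_weakest_edge(self):
        w = np.zeros((3, 3))
        w[0, 1], w[1, 2], w[0, 2] = 0.9, 0.8, 0.7
        g = ConnectomeGraph(w, list("ABC"))
        f = build_filtration(g)
        tri = [s for s in f.simplices if s.dim == 2]
        assert len(tri) == 1
        assert tri[0].rank == 3
        assert tri[0].value == pytest.approx(-np.log(0.7 / 0.9))

    def test_ties_are_deterministic(self):
        w = np.zeros((4, 4))
        for i, j in [(0, 1), (1, 2), (2, 3), (0, 3), (0, 2)]:
            w[i, j] = 0.5
        g = ConnectomeGraph(w, list("ABCD"))
        f1 = build_filtration(g)
        f2 = build_filtration(g)
        assert [s.vertices for s in f1.simplices] == [s.vertices for s in f2.simplices]
        edges = [s.vertices for s in f1.simplices if s.dim == 1]
        assert edges == sorted(edges)  # lexicographic tie-break

    def test_max_dim_bounds(self):
        g = fixture_graph("complete", 4)
        with pytest.raises(ValueError):
            build_filtration(g, max_dim=4)
        f2 = build_filtration(g, max_dim=2)
        assert max(s.dim for s in f2.simplices) == 2


class TestPersistence:
    def test_square_c4_single_immortal_h1(self):
        diag = persistent_homology(build_filtration(fixture_graph("square_c4")))
        h1 = diag.bars_in_dim(1)
        assert len(h1) == 1
        assert h1[0].birth_rank == 4
        assert np.isinf(h1[0].death_rank)
        # the representative is the 4-cycle itself
        assert sorted(h1[0].representative) == [(0, 1), (0, 3), (1, 2), (2, 3)]

    def test_octahedron_betti(self):
        diag = persistent_homology(build_filtration(fixture_graph("octahedron")))
        assert diag.betti() == (1, 0, 1)

    def test_octahedron_matches_rank_oracle(self):
        f = build_filtration(fixture_graph("octahedron"))
        expected = betti_numbers_bruteforce([s.vertices for s in f.simplices])
        assert diag_betti_prefix(f, expected)

    def test_complete_graph_contractible(self):
        diag = persistent_homology(build_filtration(fixture_graph("complete", 6)))
        assert diag.betti() == (1, 0, 0)

    def test_h0_matches_union_find_at_every_step(self):
        g = random_digraph(12, 0.15, seed=0)
        f = build_filtration(g)
        diag = persistent_homology(f)
        edges = [s.vertices for s in f.simplices if s.dim == 1]
        for rank in range(len(edges) + 1):
            assert betti_at_rank(diag, rank, 0) == h0_count_union_find(12, edges, rank)

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_betti_curve_matches_rank_oracle(self, seed):
        g = random_digraph(7, 0.45, seed=seed)
        f = build_filtration(g)
        diag = persistent_homology(f)
        for rank in range(f.n_edges + 1):
            prefix = [s.vertices for s in f.simplices if s.rank <= rank]
            oracle = betti_numbers_bruteforce(prefix)
            for dim in (0, 1, 2):
                expected = oracle[dim] if dim < len(oracle) else 0
                assert betti_at_rank(diag, rank, dim) == expected, (seed, rank, dim)

    @pytest.mark.parametrize("seed", [1, 2])
    def test_euler_characteristic_at_every_step(self, seed):
        g = random_digraph(8, 0.4, seed=seed)
        f = build_filtration(g)
        for rank in range(f.n_edges + 1):
            prefix = [s.vertices for s in f.simplices if s.rank <= rank]
            counts = np.zeros(4, dtype=int)
            for s in prefix:
                counts[len(s) - 1] += 1
            euler_simplices = counts[0] - counts[1] + counts[2] - counts[3]
            betti = betti_numbers_bruteforce(prefix)
            euler_betti = sum((-1) ** d * b for d, b in enumerate(betti))
            assert euler_simplices == euler_betti

    def test_relabeling_invariance(self):
        g = random_digraph(9, 0.3, seed=4)
        perm = np.random.default_rng(0).permutation(9)
        gp = ConnectomeGraph(g.weights[np.ix_(perm, perm)], [g.labels[i] for i in perm])
        bars_a = sorted(
            (b.dimension, b.birth_rank, b.death_rank)
            for b in persistent_homology(build_filtration(g)).bars
        )
        bars_b = sorted(
            (b.dimension, b.birth_rank, b.death_rank)
            for b in persistent_homology(build_filtration(gp)).bars
        )
        assert bars_a == bars_b

    def test_lifetimes_nonnegative_single_immortal_h0(self, geo_graph):
        diag = persistent_homology(build_filtration(geo_graph))
        assert all(b.death_rank >= b.birth_rank for b in diag.bars)
        immortal_h0 = [b for b in diag.bars_in_dim(0, include_zero_length=True) if b.immortal]
        assert len(immortal_h0) == 1  # dense graph ends connected


def diag_betti_prefix(f, expected):
    diag = persistent_homology(f)
    return diag.betti() == tuple(expected[: len(diag.betti())])


class TestCavitySignificance:
    def test_planted_ring_ranks_first(self):
        # strong 6-ring among nodes 0..5, weak clutter among nodes 6..11
        n = 12
        rng = np.random.default_rng(5)
        w = np.zeros((n, n))
        ring = [(i, (i + 1) % 6) for i in range(6)]
        for u, v in ring:
            w[u, v] = w[v, u] = 0.95
        clutter = rng.random((n, n)) < 0.25
        np.fill_diagonal(clutter, False)
        clutter[:6, :6] = False  # no chords on the ring
        w[clutter] = rng.uniform(0.05, 0.3, clutter.sum())
        g = ConnectomeGraph(w, [f"N{i:02d}" for i in range(n)])
        ens = build_ensemble(g, n_members=10, swaps_per_edge=5, seed=6)
        reports = cavity_significance(g, ens, top_m=3)
        top = reports[1].top_bars[0]
        assert set(top["nodes"]) == {f"N{i:02d}" for i in range(6)}

    def test_report_structure(self, geo_graph):
        ens = build_ensemble(geo_graph, n_members=5, swaps_per_edge=5, seed=7)
        reports = cavity_significance(geo_graph, ens, top_m=2)
        for dim in (1, 2):
            rep = reports[dim]
            assert 0 < rep.p_count <= 1
            assert 0 < rep.p_longest <= 1
            assert len(rep.top_bars) <= 2
            for bar in rep.top_bars:
                assert bar["lifetime_rank"] >= 0
                assert all(lab in geo_graph.labels for lab in bar["nodes"])

    def test_size_mismatch_rejected(self, geo_graph):
        other = random_digraph(10, 0.3, seed=8)
        ens = build_ensemble(other, n_members=3, swaps_per_edge=3, seed=9)
        with pytest.raises(ValueError):
            cavity_significance(geo_graph, ens)
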