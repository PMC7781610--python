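import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from connectocore import (
    ConnectomeGraph,
    consensus_partition,
    fixture_graph,
    generate_modular,
    louvain_partition,
    modularity_score,
    partition_nmi,
    resolution_sweep,
)
from connectocore.synthetic import SyntheticSpec

from conftest import random_digraph


class TestModularityScore:
    def test_two_cliques_closed_form(self):
        # two disconnected complete digraphs at gamma=1: Q = 1 - gamma/2 = 0.5
        g = fixture_graph("two_cliques", 8)
        labels = [0] * 4 + [1] * 4
        assert modularity_score(g, labels, 1.0) == pytest.approx(0.5)

    def test_all_in_one_community(self):
        g = random_digraph(10, 0.3, seed=0)
        w = g.weights
        m = w.sum()
        expected = 1.0 - (w.sum(axis=1).sum() * 1.0) * 0  # placeholder, computed below
        s_out, s_in = w.sum(axis=1), w.sum(axis=0)
        expected = 1.0 - float(s_out.sum() * s_in.sum()) / m**2
        assert modularity_score(g, np.zeros(10, dtype=int), 1.0) == pytest.approx(expected)

    def test_singletons_at_gamma_zero(self):
        g = random_digraph(10, 0.3, seed=1)
        assert modularity_score(g, np.arange(10), 0.0) == pytest.approx(0.0)

    def test_zero_weight_rejected(self):
        g = ConnectomeGraph(np.zeros((3, 3)), list("ABC"))
        with pytest.raises(ValueError):
            modularity_score(g, [0, 0, 0], 1.0)


class TestLouvain:
    def test_two_cliques_recovered_exactly(self):
        g = fixture_graph("two_cliques", 8)
        part = louvain_partition(g, 1.0, seed=0)
        assert part.n_communities == 2
        assert part.quality == pytest.approx(0.5)
        assert len(set(part.labels[:4])) == 1 and len(set(part.labels[4:])) == 1

    def test_beats_all_in_one_partition(self):
        g = random_digraph(20, 0.2, seed=2)
        part = louvain_partition(g, 1.0, seed=0)
        assert part.quality >= modularity_score(g, np.zeros(20, dtype=int), 1.0)

    def test_seed_determinism(self):
        g = random_digraph(20, 0.2, seed=3)
        a = louvain_partition(g, 1.0, seed=7)
        b = louvain_partition(g, 1.0, seed=7)
        np.testing.assert_array_equal(a.labels, b.labels)

    def test_labels_contiguous(self):
        g = random_digraph(15, 0.3, seed=4)
        part = louvain_partition(g, 1.5, seed=0)
        assert set(part.labels) == set(range(part.n_communities))


class TestConsensus:
    def test_deterministic_input_returns_partition(self):
        g = fixture_graph("two_cliques", 8)
        res = consensus_partition(g, 1.0, n_runs=20, seed=0)
        assert res.partition.n_communities == 2
        assert set(np.unique(res.coassignment)) <= {0.0, 1.0}

    def test_idempotent_on_consensus(self):
        spec = SyntheticSpec(
            n=30, target_density=0.3, community_sizes=[15, 15],
            within_between_ratio=8, seed=5,
        )
        g = generate_modular(spec)
        first = consensus_partition(g, 1.0, n_runs=30, seed=1)
        second = consensus_partition(g, 1.0, n_runs=30, seed=2)
        assert partition_nmi(first.partition.labels, second.partition.labels) == pytest.approx(1.0)

    def test_recovers_planted_blocks(self):
        spec = SyntheticSpec(
            n=55, target_density=0.3, community_sizes=[14, 14, 14, 13],
            within_between_ratio=8, seed=3,
        )
        g = generate_modular(spec)
        res = consensus_partition(g, 1.0, n_runs=50, seed=0)
        assert partition_nmi(res.partition.labels, g.meta["planted_labels"]) > 0.9

    def test_coassignment_invariants(self):
        g = random_digraph(15, 0.3, seed=6)
        res = consensus_partition(g, 1.0, n_runs=20, seed=0)
        co = res.coassignment
        np.testing.assert_allclose(co, co.T)
        np.testing.assert_allclose(np.diag(co), 1.0)
        assert co.min() >= 0 and co.max() <= 1

    def test_needs_two_runs(self):
        g = random_digraph(10, 0.3, seed=7)
        with pytest.raises(ValueError):
            consensus_partition(g, 1.0, n_runs=1, seed=0)


class TestNMI:
    def test_identical(self):
        a = [0, 0, 1, 1, 2]
        assert partition_nmi(a, a) == pytest.approx(1.0)

    def test_relabeling_invariant(self):
        a = [0, 0, 1, 1, 2, 2]
        b = [5, 5, 3, 3, 9, 9]
        assert partition_nmi(a, b) == pytest.approx(1.0)

    def test_independent_partitions_near_zero(self):
        rng = np.random.default_rng(0)
        vals = [
            partition_nmi(rng.integers(0, 4, 400), rng.integers(0, 4, 400))
            for _ in range(50)
        ]
        assert np.mean(vals) < 0.05

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            partition_nmi([0, 1], [0, 1, 2])

    @given(st.lists(st.integers(0, 3), min_size=2, max_size=30))
    @settings(max_examples=50, deadline=None)
    def test_symmetric(self, a):
        rng = np.random.default_rng(len(a))
        b = rng.integers(0, 3, len(a))
        assert partition_nmi(a, b) == pytest.approx(partition_nmi(b, a))

    def test_both_trivial_defined_zero(self):
        assert partition_nmi([0, 0, 0], [1, 1, 1]) == 0.0


def hierarchical_graph(seed=0):
    """4 super-blocks of 14/14/14/14, each split into two sub-blocks of 7."""
    rng = np.random.default_rng(seed)
    n = 56
    sup = np.repeat(np.arange(4), 14)
    sub = np.repeat(np.arange(8), 7)
    p = np.full((n, n), 0.02)
    p[sup[:, None] == sup[None, :]] = 0.25
    p[sub[:, None] == sub[None, :]] = 0.85
    w = (rng.random((n, n)) < p) * rng.lognormal(0, 0.5, (n, n))
    np.fill_diagonal(w, 0)
    w /= w.max()
    g = ConnectomeGraph(w, [f"N{i:02d}" for i in range(n)])
    g.meta["super"] = sup
    g.meta["sub"] = sub
    return g


class TestResolutionSweep:
    def test_hierarchical_coarse_and_fine_scales(self):
        g = hierarchical_graph(seed=1)
        low = consensus_partition(g, 0.5, n_runs=30, seed=0)
        high = consensus_partition(g, 2.0, n_runs=30, seed=0)
        assert partition_nmi(low.partition.labels, g.meta["super"]) > 0.9
        assert partition_nmi(high.partition.labels, g.meta["sub"]) > 0.9

    def test_sweep_structure(self):
        g = hierarchical_graph(seed=2)
        sweep = resolution_sweep(g, [0.5, 1.0, 1.5, 2.0], n_runs=15, seed=0)
        assert sweep.nmi_matrix.shape == (4, 4)
        np.testing.assert_allclose(np.diag(sweep.nmi_matrix), 1.0)
        np.testing.assert_allclose(sweep.nmi_matrix, sweep.nmi_matrix.T)
        counts = [r.partition.n_communities for r in sweep.results]
        assert counts[0] <= counts[-1]  # finer scales at higher resolution

    def test_single_point_grid(self):
        g = random_digraph(15, 0.3, seed=8)
        sweep = resolution_sweep(g, [1.0], n_runs=10, seed=0)
        assert len(sweep.results) == 1
        assert sweep.selected_gammas == [1.0]

    def test_empty_grid_rejected(self):
        g = random_digraph(10, 0.3, seed=9)
        with pytest.raises(ValueError):
            resolution_sweep(g, [], n_runs=5, seed=0)
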