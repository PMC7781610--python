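import numpy as np
import pytest

from connectocore import ConnectomeGraph, build_ensemble, generate_geometric
from connectocore.synthetic import SyntheticSpec


def random_digraph(n, density, seed, weighted=True):
    """Erdos-Renyi style weighted digraph for oracle comparisons."""
    rng = np.random.default_rng(seed)
    w = (rng.random((n, n)) < density).astype(float)
    if weighted:
        w *= rng.random((n, n))
    np.fill_diagonal(w, 0.0)
    return ConnectomeGraph(w, [f"N{i:02d}" for i in range(n)])


@pytest.fixture(scope="session")
def geo_graph():
    """Mid-size geometric connectome shared across expensive tests."""
    return generate_geometric(SyntheticSpec(n=40, target_density=0.3, seed=7))


@pytest.fixture(scope="session")
def geo_ensemble(geo_graph):
    return build_ensemble(geo_graph, n_members=30, swaps_per_edge=10, seed=11)
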