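import networkx as nx
import numpy as np
import pytest

from minecomplex.synthetic import SyntheticSpec, generate


@pytest.fixture(scope="session")
def recovery_bundle():
    """Planted-complex benchmark at the reference recovery conditions."""
    return generate(
        SyntheticSpec(p_in=0.95, p_out=0.01, leak_rate=0.05, n_complexes=10, seed=7)
    )


@pytest.fixture(scope="session")
def default_bundle():
    """Planted-complex benchmark at generator defaults."""
    return generate(SyntheticSpec(seed=11))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_weighted_graph(rng, n_nodes, p=0.4):
    """Small random weighted graph with lexicographically sortable labels."""
    g = nx.Graph(relation="PPIN")
    labels = [f"v{i:02d}" for i in range(n_nodes)]
    g.add_nodes_from(labels)
    for i in range(n_nodes):
        for j in range(i + 1, n_nodes):
            if rng.random() < p:
                g.add_edge(labels[i], labels[j], weight=float(rng.uniform(0.05, 1.0)))
    return g
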