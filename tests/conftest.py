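import networkx as nx
import numpy as np
import pytest

import kdconn as k


def make_random_graph(n_nodes: int, m: int, seed: int) -> k.BinaryGraph:
    g = nx.gnm_random_graph(n_nodes, m, seed=seed)
    return k.BinaryGraph.from_networkx(g)


def make_sbm(sizes, p_in, p_out, seed) -> tuple[k.BinaryGraph, np.ndarray]:
    """Planted-partition stochastic block model and its planted labels."""
    blocks = len(sizes)
    probs = [[p_in if i == j else p_out for j in range(blocks)] for i in range(blocks)]
    g = nx.stochastic_block_model(sizes, probs, seed=seed)
    labels = np.repeat(np.arange(blocks), sizes)
    return k.BinaryGraph.from_networkx(g), labels


@pytest.fixture(scope="session")
def default_spec() -> k.ModularCovSpec:
    return k.ModularCovSpec()


@pytest.fixture(scope="session")
def healthy_cohort(default_spec):
    """20 synthetic control subjects (shared across tests; read-only)."""
    return k.gen_cohort(default_spec, 20, seed=42)


@pytest.fixture(scope="session")
def healthy_profiles(healthy_cohort):
    return [
        k.degree(
            k.threshold_to_density(k.correlation_matrix(ts), 0.1),
            subject_id=ts.subject_id,
        )
        for ts in healthy_cohort
    ]


@pytest.fixture(scope="session")
def healthy_reference(healthy_profiles):
    return k.reference_degree_map(healthy_profiles, cohort_id="control")


@pytest.fixture
def two_cliques() -> k.BinaryGraph:
    g = nx.disjoint_union(nx.complete_graph(5), nx.complete_graph(5))
    return k.BinaryGraph.from_networkx(g)


@pytest.fixture
def triangle() -> k.BinaryGraph:
    return k.BinaryGraph(n_nodes=3, edges=np.array([[0, 1], [0, 2], [1, 2]]), density=1.0)


@pytest.fixture
def path3() -> k.BinaryGraph:
    return k.BinaryGraph(n_nodes=3, edges=np.array([[0, 1], [1, 2]]), density=2 / 3)
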