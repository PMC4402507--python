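import networkx as nx
import numpy as np
import pandas as pd
import pytest

from netdriver.io_model import (
    ExpressionMatrix,
    GeneNetwork,
    MutationMatrix,
    ParameterSet,
)
from netdriver.synthetic import generate_cohort, generate_network


@pytest.fixture
def chain_network() -> GeneNetwork:
    """A - B - C path graph."""
    return GeneNetwork.from_edges([("A", "B"), ("B", "C")])


@pytest.fixture
def default_params() -> ParameterSet:
    return ParameterSet(L=2, D=50, F=2.0)


@pytest.fixture(scope="session")
def small_cohort():
    """Scaled-down synthetic cohort for end-to-end unit tests.

    300-gene network, 20 tumors, 15 normals, 4-driver pool; fast enough for
    repeated pipeline runs within the suite.
    """
    net = generate_network(n_genes=300, seed=7)
    sc = generate_cohort(
        net,
        n_samples=20,
        n_normals=15,
        seed=7,
        driver_pool_size=4,
    )
    return net, sc


def make_expression(values: np.ndarray, genes, samples, scale="log2") -> ExpressionMatrix:
    return ExpressionMatrix(pd.DataFrame(values, index=genes, columns=samples), scale=scale)


def make_mutations(pairs, genes, samples) -> MutationMatrix:
    df = pd.DataFrame(0, index=genes, columns=samples, dtype=np.int8)
    for g, s in pairs:
        df.loc[g, s] = 1
    return MutationMatrix(df)


def random_graph_and_sets(rng, n_max=12):
    """Small random graph with a deregulated subset and a mutated source."""
    n = int(rng.integers(4, n_max + 1))
    g = nx.gnp_random_graph(n, 0.4, seed=int(rng.integers(2**31 - 1)))
    g = nx.relabel_nodes(g, {i: f"g{i}" for i in g.nodes})
    nodes = sorted(g.nodes)
    dereg = {v for v in nodes if rng.random() < 0.5}
    source = nodes[int(rng.integers(len(nodes)))]
    return GeneNetwork(g), dereg, source
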