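import numpy as np
import pandas as pd
import pytest

from urbanocc import causal, synthetic


@pytest.fixture(scope="session")
def small_landscape():
    return synthetic.generate_landscape(n_sites=20, grid_shape=(15, 15), seed=7)


@pytest.fixture(scope="session")
def single_predictor_spec():
    return causal.ModelSpec("Phoridae", "d_ocean", ("d_ocean",), (), 0.25)


@pytest.fixture(scope="session")
def small_survey(small_landscape, single_predictor_spec):
    truth = synthetic.generate_community(
        12, seed=5, predictors=("d_ocean",), mu_slope={"d_ocean": -0.5}
    )
    data = synthetic.simulate_detections(truth, small_landscape, seed=6)
    cov = synthetic.standardize_sites(small_landscape, ("d_ocean",))
    return truth, data, cov


def random_dag(rng, n_nodes=None, p_edge=0.35):
    """A random DAG on a topological node order (edges i -> j for i < j)."""
    import networkx as nx

    n = n_nodes or int(rng.integers(3, 8))
    g = nx.DiGraph()
    g.add_nodes_from(range(n))
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p_edge:
                g.add_edge(i, j)
    return g
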