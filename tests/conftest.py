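import numpy as np
import pytest
from hypothesis import settings

import mccsp

settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("ci")

#: seed used by all deterministic test scenarios
TEST_SEED = 1


def random_dag(rng: np.random.Generator, n_nodes: int):
    """Random weighted DAG: a guaranteed chain plus forward skip edges.

    Returns (DirectedNetwork, strengths dict).  Node 0 is the source and the
    last node the sink, so the source has in-degree 0 and the sink out-degree
    0 by construction.
    """
    names = [f"n{i:02d}" for i in range(n_nodes)]
    edges = list(zip(names[:-1], names[1:]))
    for i in range(n_nodes):
        for j in range(i + 2, n_nodes):
            if rng.random() < 0.35:
                edges.append((names[i], names[j]))
    net = mccsp.DirectedNetwork(names, edges, source=names[0], sink=names[-1])
    strengths = {e: float(rng.uniform(0.05, 1.0)) for e in net.edges}
    return net, strengths


@pytest.fixture(scope="session")
def linear_scenario():
    return mccsp.make_scenario(nonlinear_fraction=0.0, sample_size=500,
                               replicates=500, seed=TEST_SEED)


@pytest.fixture(scope="session")
def linear_population(linear_scenario):
    return mccsp.generate_population(linear_scenario)


@pytest.fixture(scope="session")
def linear_truth(linear_scenario, linear_population):
    return mccsp.true_top_pathways(linear_scenario, linear_population)


@pytest.fixture(scope="session")
def fan_net():
    return mccsp.fan_network()
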