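import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import grndyn as g
from grndyn.network import GeneNetwork

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def bifurcating_net() -> GeneNetwork:
    return g.benchmark_network("bifurcating")


@pytest.fixture(scope="session")
def damaged_net(bifurcating_net) -> GeneNetwork:
    """The canonical damage: the activating edge from g3 onto the g5 arm."""
    return g.remove_edge(bifurcating_net, "g3", "g5")


@pytest.fixture(scope="session")
def bifurcating_data(bifurcating_net) -> g.ExpressionDataset:
    """Cells simulated on the true bifurcating topology (scaled-down size)."""
    return g.simulate_cells(
        bifurcating_net, g.SimulationConfig(n_cells=500, seed=11)
    )


@pytest.fixture(scope="session")
def planted_block():
    """Two dense blocks of 12 nodes with block-indicator features.

    Within-block edges are the signal a link predictor should pick up; the
    features tell the two blocks apart up to small noise.
    """
    rng = np.random.default_rng(0)
    m, block = 24, 12
    genes = tuple(f"g{i + 1}" for i in range(m))
    edges = set()
    for b in range(2):
        nodes = range(b * block, (b + 1) * block)
        for i in nodes:
            for j in nodes:
                if i != j and rng.random() < 0.45:
                    edges.add((genes[i], genes[j]))
    net = GeneNetwork(genes, frozenset(edges))
    X = np.zeros((m, 40))
    X[:block, :20] = 1.0
    X[block:, 20:] = 1.0
    X += 0.1 * rng.standard_normal(X.shape)
    return net, X
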