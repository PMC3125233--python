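import numpy as np
import pytest

from pcenet.network import Network, Node, Pipe
from pcenet.synth import TownConfig, generate_town


@pytest.fixture
def y_tree():
    """Source feeding A, which splits to B (demand 1) and C (demand 2)."""
    nodes = [Node("S", 0, 0, "source"),
             Node("A", 1, 0, demand=0.0),
             Node("B", 2, 0, demand=1.0),
             Node("C", 2, 1, demand=2.0)]
    pipes = [Pipe("p1", "S", "A", 100, 0.2),
             Pipe("p2", "A", "B", 100, 0.2),
             Pipe("p3", "A", "C", 100, 0.2)]
    return Network(nodes, pipes)


@pytest.fixture
def parallel_net():
    """Two identical pipes between the source and one demand node."""
    nodes = [Node("S", 0, 0, "source"), Node("J", 1, 0, demand=4.0)]
    pipes = [Pipe("pa", "S", "J", 100, 0.2), Pipe("pb", "S", "J", 100, 0.2)]
    return Network(nodes, pipes)


@pytest.fixture
def asym_loop():
    """4-node loop with unequal diameters: S -> A -> C and S -> B -> C."""
    nodes = [Node("S", 0, 0, "source"),
             Node("A", 1, 1, demand=1.0),
             Node("B", 1, -1, demand=1.0),
             Node("C", 2, 0, demand=4.0)]
    pipes = [Pipe("sa", "S", "A", 100, 0.30),
             Pipe("sb", "S", "B", 100, 0.15),
             Pipe("ac", "A", "C", 100, 0.30),
             Pipe("bc", "B", "C", 100, 0.15)]
    return Network(nodes, pipes)


@pytest.fixture(scope="session")
def grid5_town():
    """5x5 grid, no branches: 25 nodes, 40 pipes."""
    return generate_town(TownConfig(grid_rows=5, grid_cols=5, n_branches=0,
                                    acvl_fraction=0.2, seed=11))


@pytest.fixture(scope="session")
def small_town():
    return generate_town(TownConfig(seed=7))


def random_tree_network(rng: np.random.Generator, n_nodes: int) -> Network:
    """Random spanning tree rooted at one source, random demands."""
    nodes = [Node("S", 0.0, 0.0, "source")]
    pipes = []
    ids = ["S"]
    for i in range(1, n_nodes):
        parent = ids[int(rng.integers(len(ids)))]
        nid = f"N{i}"
        nodes.append(Node(nid, float(i), float(rng.random()),
                          demand=float(rng.uniform(0.1, 5.0))))
        pipes.append(Pipe(f"e{i}", parent, nid,
                          float(rng.uniform(50, 500)),
                          float(rng.uniform(0.1, 0.4))))
        ids.append(nid)
    return Network(nodes, pipes)
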