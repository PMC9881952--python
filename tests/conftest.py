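import numpy as np
import pytest

import permprior as pp


@pytest.fixture
def path4() -> pp.Network:
    """Undirected path a-b-c-d: degree sequence (1, 2, 2, 1)."""
    return pp.Network(frozenset({(0, 1), (1, 2), (2, 3)}), 4, 4)


@pytest.fixture
def triangle() -> pp.Network:
    """Undirected triangle: its degree sequence admits exactly one graph."""
    return pp.Network(frozenset({(0, 1), (1, 2), (0, 2)}), 3, 3)


@pytest.fixture
def complete4() -> pp.Network:
    edges = frozenset((i, j) for i in range(4) for j in range(i + 1, 4))
    return pp.Network(edges, 4, 4)


@pytest.fixture
def star6() -> pp.Network:
    """Hub 0 connected to leaves 1..5 (degrees 5, 1, 1, 1, 1, 1)."""
    return pp.Network(frozenset((0, j) for j in range(1, 6)), 6, 6)


@pytest.fixture
def bipartite23() -> pp.Network:
    """Complete bipartite 2 x 3."""
    edges = frozenset((i, j) for i in range(2) for j in range(3))
    return pp.Network(edges, 2, 3, bipartite=True)


def random_directed(n: int, m: int, seed: int, antiparallel: bool = False) -> pp.Network:
    rng = np.random.default_rng(seed)
    edges: set = set()
    while len(edges) < m:
        i, j = (int(x) for x in rng.integers(0, n, 2))
        if i == j or (i, j) in edges:
            continue
        if not antiparallel and (j, i) in edges:
            continue
        edges.add((i, j))
    return pp.Network(
        frozenset(edges), n, n, directed=True, allow_antiparallel=antiparallel
    )


def with_loops(network: pp.Network, loops, seed: int = 0) -> pp.Network:
    edges = set(network.edges) | {(i, i) for i in loops}
    return pp.Network(
        frozenset(edges),
        network.n_source,
        network.n_target,
        network.directed,
        network.bipartite,
        allow_loops=True,
        allow_antiparallel=network.allow_antiparallel,
    )


@pytest.fixture
def structural_fixtures() -> list:
    """One network per structural kind, for degree-preservation sweeps."""
    undirected = pp.generate_network(
        pp.GeneratorConfig(n_source=60, m=120, heterogeneity=1.0, seed=10)
    )
    loopy = with_loops(
        pp.generate_network(
            pp.GeneratorConfig(n_source=40, m=70, heterogeneity=0.5, seed=11)
        ),
        loops=(0, 3, 7),
    )
    directed = random_directed(40, 80, seed=12)
    anti = random_directed(30, 70, seed=13, antiparallel=True)
    bipartite = pp.generate_network(
        pp.GeneratorConfig(n_source=20, m=100, n_target=30, heterogeneity=1.0, seed=14)
    )
    return [undirected, loopy, directed, anti, bipartite]
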