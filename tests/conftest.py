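from itertools import combinations

import pytest

from modrec.graph import WeightedGraph


def clique(names, weight=1.0):
    g = WeightedGraph()
    for v in names:
        g.add_node(v)
    for u, v in combinations(names, 2):
        g.add_edge(u, v, weight)
    return g


def ring(n, weight=1.0, prefix="r"):
    g = WeightedGraph()
    names = [f"{prefix}{i:02d}" for i in range(n)]
    for i in range(n):
        g.add_edge(names[i], names[(i + 1) % n], weight)
    return g


@pytest.fixture
def triangle():
    return clique(["a", "b", "c"])


@pytest.fixture
def two_triangles():
    g = clique(["a", "b", "c"])
    for u, v in combinations(["d", "e", "f"], 2):
        g.add_edge(u, v, 1.0)
    return g


@pytest.fixture
def barbell():
    """Two unit-weight K4 cliques joined by a single bridge edge."""
    g = clique(["a", "b", "c", "d"])
    for u, v in combinations(["e", "f", "g", "h"], 2):
        g.add_edge(u, v, 1.0)
    g.add_edge("d", "e", 1.0)
    return g


@pytest.fixture
def path_abc():
    g = WeightedGraph()
    g.add_edge("a", "b", 1.0)
    g.add_edge("b", "c", 1.0)
    return g


@pytest.fixture
def k5():
    return clique(list("abcde"))


@pytest.fixture
def star_k13():
    g = WeightedGraph()
    for leaf in ["l1", "l2", "l3"]:
        g.add_edge("c", leaf, 1.0)
    return g
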