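import numpy as np
import pytest

from linkbench import Graph, CandidatePairSet


@pytest.fixture
def K2():
    return Graph.from_label_edges([("a", "b")])


@pytest.fixture
def P3():
    return Graph.from_label_edges([("a", "b"), ("b", "c")])


@pytest.fixture
def G1():
    """4-node fixture: edges (1,2),(1,3),(2,3),(3,4); degrees 2,2,3,1."""
    return Graph.from_label_edges([("1", "2"), ("1", "3"), ("2", "3"), ("3", "4")])


def er_graph(n: int, p: float, seed: int) -> Graph:
    """Seeded Erdos-Renyi graph (independent of the package generators)."""
    rng = np.random.default_rng(seed)
    upper = np.triu(rng.random((n, n)) < p, k=1)
    ii, jj = np.nonzero(upper)
    edges = {(int(i), int(j)) for i, j in zip(ii, jj)}
    return Graph(node_labels=[str(i) for i in range(n)], edges=edges)


def all_pairs(g: Graph) -> CandidatePairSet:
    pairs = [(i, j) for i in range(g.n) for j in range(i + 1, g.n)]
    return CandidatePairSet(pairs=pairs)
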