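"""Shared fixtures: toy networks, printed operator agents, scripted RNG."""

from __future__ import annotations

import numpy as np
import pytest

from maefmd import Agent, ModuleSet, PPINetwork, build_strength_table


class ScriptedRng:
    """Deterministic stand-in for numpy's Generator in operator tests.

    ``integers(n)`` and ``random()`` pop pre-scripted values, letting a test
    force each random choice of an operator and assert the printed outcome.
    """

    def __init__(self, ints=(), reals=()):
        self._ints = list(ints)
        self._reals = list(reals)

    def integers(self, n: int) -> int:
        v = self._ints.pop(0)
        assert 0 <= v < n, f"scripted draw {v} out of range({n})"
        return v

    def random(self) -> float:
        return self._reals.pop(0)


# Eight-node toy network covering every link used by the operator worked
# examples; labels are '1'..'8' so node index = label - 1.
TOY8_EDGES = [
    ("1", "2"), ("1", "3"), ("1", "5"), ("1", "6"), ("1", "7"),
    ("2", "3"), ("2", "4"), ("2", "5"), ("2", "7"), ("2", "8"),
    ("3", "7"), ("3", "8"),
    ("4", "7"), ("4", "8"),
    ("5", "6"), ("5", "7"),
    ("6", "8"),
]


@pytest.fixture(scope="session")
def toy8() -> PPINetwork:
    return PPINetwork(TOY8_EDGES)


@pytest.fixture(scope="session")
def toy8_table(toy8):
    return build_strength_table(toy8, ann=None, epsilon=0.0)


def agent_from(net: PPINetwork, targets: str) -> Agent:
    """Build an agent from a compact '6 2 7 8 5 5 2 8' target-label string."""
    labels = targets.split()
    links = {str(i + 1): labels[i] for i in range(len(labels))}
    return Agent.from_links(net, links)


@pytest.fixture(scope="session")
def two_triangles() -> tuple[PPINetwork, ModuleSet]:
    """Two K3 cliques joined by one bridge; optimum = the two triangles."""
    net = PPINetwork(
        [("a", "b"), ("a", "c"), ("b", "c"), ("d", "e"), ("d", "f"), ("e", "f"), ("c", "d")]
    )
    truth = ModuleSet([{"a", "b", "c"}, {"d", "e", "f"}])
    return net, truth


def enumerate_partitions(items: list):
    """All set partitions of ``items`` (Bell-number many; fine for n <= 8)."""
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in enumerate_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [part[i] + [first]] + part[i + 1 :]
        yield [[first]] + part


def recount_modularity(net: PPINetwork, partition: ModuleSet) -> float:
    """Brute-force modularity: recount e_c and d_c per module from scratch."""
    m = net.num_edges
    total = 0.0
    for module in partition:
        members = sorted(module)
        e_c = sum(
            1
            for i, a in enumerate(members)
            for b in members[i + 1 :]
            if net.graph.has_edge(a, b)
        )
        d_c = sum(net.graph.degree(p) for p in members)
        total += e_c / m - (d_c / (2.0 * m)) ** 2
    return total


def random_connected_network(rng: np.random.Generator, n_max: int = 7) -> PPINetwork:
    """A random connected graph with 4..n_max nodes and >= 2 edges."""
    import networkx as nx

    while True:
        n = int(rng.integers(4, n_max + 1))
        g = nx.gnp_random_graph(n, 0.5, seed=int(rng.integers(2**31)))
        if nx.is_connected(g) and g.number_of_edges() >= 2:
            return PPINetwork([(str(a), str(b)) for a, b in g.edges])
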