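"""Connection-based partition encoding and its random-walk construction.

An agent encodes one candidate partition of the network as a length-N
vector: entry ``a_i`` is the node that node ``i`` points at, restricted to
``Γ(i) ∪ {i}``.  Nodes connected through these links fall into the same
module, so decoding is just connected components of the link graph; a node
pointing at itself (a *breakpoint*) marks a module boundary.  Partition
quality ("energy") is Newman modularity

    Energy(A) = Σ_c [ e_c/|E| − (d_c / 2|E|)² ]

over the decoded modules c, where e_c counts intra-module interactions and
d_c sums member degrees.  Energy lies in [-0.5, 1] for any partition.
"""

from __future__ import annotations

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

from .io import ModuleSet, PPINetwork
from .similarity import StrengthTable

__all__ = ["Agent", "decode", "energy", "partition_energy", "construct_agent"]


class Agent:
    """One candidate solution: a feasible connection vector over the network.

    ``assignment`` is an integer array over the network's sorted node
    ordering; ``assignment[i]`` is the node index that node ``i`` links to.
    Energy is computed lazily and cached; it is invalidated whenever the
    assignment is replaced.
    """

    __slots__ = ("net", "assignment", "_energy")

    def __init__(self, net: PPINetwork, assignment: np.ndarray, *, validate: bool = True):
        assignment = np.asarray(assignment, dtype=np.int64)
        if validate:
            _check_feasible(net, assignment)
        self.net = net
        self.assignment = assignment
        self._energy: float | None = None

    @classmethod
    def from_links(cls, net: PPINetwork, links: dict[str, str]) -> "Agent":
        """Build an agent from a {protein: linked-protein} mapping."""
        a = np.empty(net.num_nodes, dtype=np.int64)
        for i, node in enumerate(net.node_order):
            a[i] = net.index(links[node])
        return cls(net, a)

    def links(self) -> dict[str, str]:
        order = self.net.node_order
        return {order[i]: order[int(t)] for i, t in enumerate(self.assignment)}

    @property
    def energy(self) -> float:
        if self._energy is None:
            self._energy = energy(self)
        return self._energy

    def copy(self) -> "Agent":
        clone = Agent(self.net, self.assignment.copy(), validate=False)
        clone._energy = self._energy
        return clone

    def replace(self, position: int, target: int) -> None:
        """Point node ``position`` at node ``target``, invalidating energy."""
        self.assignment[position] = target
        self._energy = None

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Agent):
            return NotImplemented
        return self.net is other.net and np.array_equal(self.assignment, other.assignment)

    def __len__(self) -> int:
        return len(self.assignment)


def _check_feasible(net: PPINetwork, assignment: np.ndarray) -> None:
    if assignment.shape != (net.num_nodes,):
        raise ValueError("assignment length must equal the number of network nodes")
    order = net.node_order
    for i, t in enumerate(assignment):
        t = int(t)
        if t == i:
            continue
        if order[t] not in net.graph[order[i]]:
            raise ValueError(
                f"infeasible assignment: {order[i]} -> {order[t]} is not an interaction"
            )


def _component_labels(agent: Agent) -> tuple[np.ndarray, int]:
    n = len(agent)
    a = agent.assignment
    idx = np.arange(n)
    mask = a != idx
    rows = idx[mask]
    cols = a[mask]
    m = coo_matrix((np.ones(rows.size), (rows, cols)), shape=(n, n))
    k, labels = connected_components(m, directed=False)
    return labels, k


def decode(agent: Agent) -> ModuleSet:
    """Connected components of the link graph: the encoded partition."""
    labels, k = _component_labels(agent)
    groups: list[list[str]] = [[] for _ in range(k)]
    for i, lab in enumerate(labels):
        groups[lab].append(agent.net.node_order[i])
    return ModuleSet(groups)


def energy(agent: Agent) -> float:
    """Newman modularity of the decoded partition (in [-0.5, 1])."""
    labels, k = _component_labels(agent)
    return _modularity_from_labels(agent.net, labels, k)


def _modularity_from_labels(net: PPINetwork, labels: np.ndarray, k: int) -> float:
    m = net.num_edges
    if m == 0:
        raise ValueError("energy is undefined for an edgeless network")
    u = net.edge_index[:, 0]
    v = net.edge_index[:, 1]
    same = labels[u] == labels[v]
    e_c = np.bincount(labels[u[same]], minlength=k).astype(np.float64)
    d_c = np.bincount(labels, weights=net.degree_array, minlength=k)
    return float(np.sum(e_c / m - (d_c / (2.0 * m)) ** 2))


def partition_energy(net: PPINetwork, partition: ModuleSet) -> float:
    """Modularity of an arbitrary partition given as protein sets.

    Convenience for evaluating partitions that did not come from an agent
    (e.g. exhaustive-search oracles or reference complex sets).
    """
    if not partition.is_partition() or partition.proteins() != frozenset(net.node_order):
        raise ValueError("input must be a partition of the network's node set")
    labels = np.empty(net.num_nodes, dtype=np.int64)
    for c, module in enumerate(partition):
        for p in module:
            labels[net.index(p)] = c
    return _modularity_from_labels(net, labels, len(partition.modules))


def construct_agent(net: PPINetwork, table: StrengthTable, rng: np.random.Generator) -> Agent:
    """Build a feasible agent by repeated strength-guided random walks.

    Each traversal starts at a uniformly chosen still-unassigned node and
    steps to neighbors with probability proportional to the combined
    strength, skipping nodes already visited in the current traversal and
    edges below the ε gate.  Stepping onto a node that an earlier traversal
    already assigned ends the traversal (chains merge there); having no
    feasible step ends it with a breakpoint (``a_i = i``).
    """
    n = net.num_nodes
    if n == 0:
        raise ValueError("cannot construct an agent over an empty network")
    assignment = np.full(n, -1, dtype=np.int64)
    unassigned = sorted(range(n))
    while unassigned:
        start = unassigned[int(rng.integers(len(unassigned)))]
        visited = {start}
        cur = start
        while True:
            nbrs, strengths = table.gated_neighbors(net, cur)
            if nbrs.size:
                keep = np.array([j not in visited for j in nbrs])
                nbrs, strengths = nbrs[keep], strengths[keep]
            if nbrs.size == 0:
                assignment[cur] = cur
                break
            total = strengths.sum()
            probs = strengths / total if total > 0 else np.full(nbrs.size, 1.0 / nbrs.size)
            j = int(nbrs[np.searchsorted(np.cumsum(probs), rng.random(), side="right").clip(max=nbrs.size - 1)])
            assignment[cur] = j
            if assignment[j] != -1:
                break
            visited.add(j)
            cur = j
        unassigned = [i for i in unassigned if assignment[i] == -1]
    return Agent(net, assignment, validate=False)
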