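"""Toroidal agent lattice, evolutionary operators and the iteration engine.

The population of M agents lives on an m×m torus (M = m²).  Each sweep a
cell first competes against its best von-Neumann neighbor — the loser's
cell is re-occupied by a clone of the winner improved with the loser's
stronger links — then, with probability p_c, crosses over with a random
neighbor (both the alternating-link and alternating-chunk rules; the best
child replaces the agent only on strict energy improvement), and finally,
with probability p_m, undergoes a self-adaptive mutation whose digit count
grows with network size and with how long the agent has stagnated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace as dc_replace

import numpy as np

from .agent import Agent, construct_agent
from .io import AnnotationMap, PPINetwork
from .similarity import StrengthTable, build_strength_table

__all__ = [
    "Params",
    "PRESETS",
    "lattice_neighbors",
    "link_strengths",
    "competition",
    "crossover_alternating_link",
    "crossover_alternating_chunk",
    "mutation_count",
    "mutate",
    "EvolutionResult",
    "evolve",
]


@dataclass(frozen=True)
class Params:
    """All tunables of the detector.

    Defaults follow the curated-network preset (DIP-style data): a 10×10
    lattice, walk gate ε=0.27, stagnation horizon R=60 iterations,
    occupying/crossover probabilities 0.5, mutation probability 0.8,
    module-merging threshold λ=0.21 and density filter δ=0.04.  ω=0.2 is
    the usual neighborhood-affinity match threshold.
    """

    M: int = 100
    epsilon: float = 0.27
    R: int = 60
    p_o: float = 0.5
    p_c: float = 0.5
    p_m: float = 0.8
    lambda_merge: float = 0.21
    delta_filter: float = 0.04
    omega: float = 0.2
    max_iter: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        m = math.isqrt(self.M)
        if self.M < 4 or m * m != self.M:
            raise ValueError("population size M must be a perfect square >= 4")
        for name in ("p_o", "p_c", "p_m"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if not 0.0 < self.omega <= 1.0:
            raise ValueError("omega must lie in (0, 1]")

    @property
    def m(self) -> int:
        return math.isqrt(self.M)

    def with_overrides(self, **kwargs) -> "Params":
        return dc_replace(self, **kwargs)


#: Parameter presets tuned per source database (population size, walk gate,
#: stagnation horizon, operator probabilities, post-processing thresholds).
PRESETS: dict[str, Params] = {
    "gavin": Params(M=225, epsilon=0.25, R=60, p_o=0.5, p_c=0.5, p_m=0.8,
                    lambda_merge=1.8, delta_filter=0.12),
    "dip": Params(M=100, epsilon=0.27, R=60, p_o=0.5, p_c=0.5, p_m=0.8,
                  lambda_merge=0.21, delta_filter=0.04),
    "mips": Params(M=100, epsilon=0.27, R=60, p_o=0.5, p_c=0.5, p_m=0.8,
                   lambda_merge=0.19, delta_filter=0.05),
    "dip-scere2014": Params(M=100, epsilon=0.29, R=60, p_o=0.5, p_c=0.5, p_m=0.8,
                            lambda_merge=0.6, delta_filter=0.05),
    "dip-hsapi2014": Params(M=100, epsilon=0.28, R=60, p_o=0.5, p_c=0.5, p_m=0.8,
                            lambda_merge=0.6, delta_filter=0.05),
}


def lattice_neighbors(m: int, u: int, v: int) -> list[tuple[int, int]]:
    """The four toroidal von-Neumann neighbors of 1-based cell (u, v).

    Duplicate positions arising from wrap-around on tiny lattices (m=2)
    are deduplicated; order is deterministic (sorted)."""
    if not (1 <= u <= m and 1 <= v <= m):
        raise ValueError(f"cell ({u},{v}) outside a {m}x{m} lattice")
    up = (u - 1 + m - 1) % m + 1
    vp = (v - 1 + m - 1) % m + 1
    uq = u % m + 1
    vq = v % m + 1
    return sorted({(up, v), (u, vp), (uq, v), (u, vq)} - {(u, v)})


def link_strengths(agent: Agent, table: StrengthTable) -> np.ndarray:
    """Per-node connection strengths Al_i = strength(i, a_i); 0 at breakpoints."""
    order = agent.net.node_order
    out = np.zeros(len(agent), dtype=np.float64)
    for i, t in enumerate(agent.assignment):
        t = int(t)
        if t != i:
            out[i] = table.lookup(order[i], order[t])
    return out


def competition(
    current: Agent,
    best_neighbor: Agent,
    table: StrengthTable,
    p_o: float,
    rng: np.random.Generator,
) -> Agent:
    """Winner-survives competition against the best lattice neighbor.

    If the current agent's energy is at least the neighbor's, it survives
    unchanged.  Otherwise the neighbor occupies the cell with a clone
    improved by the loser's stronger links: with probability ``p_o`` only
    the clone's weakest link is considered for replacement (Strategy 1,
    ties at the minimum broken by lowest node index), otherwise every link
    where the loser is stronger is replaced (Strategy 2).
    """
    if current.net is not best_neighbor.net:
        raise ValueError("agents must live on the same network")
    if current.energy >= best_neighbor.energy:
        return current
    al = link_strengths(current, table)
    hl = link_strengths(best_neighbor, table)
    clone = best_neighbor.copy()
    if rng.random() < p_o:  # Strategy 1
        j = int(np.argmin(hl))  # argmin takes the first (lowest index) at ties
        if al[j] > hl[j]:
            clone.replace(j, int(current.assignment[j]))
    else:  # Strategy 2
        for i in np.nonzero(al > hl)[0]:
            clone.replace(int(i), int(current.assignment[i]))
    return clone


def _pick_unassigned(unassigned: list[int], rng) -> int:
    return unassigned[int(rng.integers(len(unassigned)))]


def crossover_alternating_link(parent1: Agent, parent2: Agent, rng) -> Agent:
    """Build a child link-by-link on a chain, alternating source parents.

    Starting from a random node the child takes that node's link from
    parent 1, follows it, takes the next node's link from parent 2, and so
    on.  Whenever the chain runs onto an already-assigned node (which would
    close a cycle in the partial tour) it restarts at a uniformly random
    unassigned node, keeping the alternation going.  Every child link comes
    from one of the parents, so feasibility is inherited.
    """
    n = len(parent1)
    parents = (parent1.assignment, parent2.assignment)
    child = np.full(n, -1, dtype=np.int64)
    unassigned = list(range(n))
    cur = _pick_unassigned(unassigned, rng)
    turn = 0
    while unassigned:
        child[cur] = parents[turn][cur]
        unassigned.remove(cur)
        turn ^= 1
        nxt = int(child[cur])
        if not unassigned:
            break
        cur = nxt if child[nxt] == -1 else _pick_unassigned(unassigned, rng)
    return Agent(parent1.net, child, validate=False)


def crossover_alternating_chunk(parent1: Agent, parent2: Agent, rng) -> Agent:
    """Assemble a child from alternating random-length parent chunks.

    Each chunk's length is drawn uniformly from 1..(nodes still
    unassigned); within a chunk links are taken chain-wise from the active
    parent with the same cycle-avoidance restart rule as the alternating
    link crossover.
    """
    n = len(parent1)
    parents = (parent1.assignment, parent2.assignment)
    child = np.full(n, -1, dtype=np.int64)
    unassigned = list(range(n))
    turn = 0
    cur: int | None = None
    while unassigned:
        chunk = 1 + int(rng.integers(len(unassigned)))
        for _ in range(chunk):
            if cur is None or child[cur] != -1:
                cur = _pick_unassigned(unassigned, rng)
            child[cur] = parents[turn][cur]
            unassigned.remove(cur)
            nxt = int(child[cur])
            cur = nxt if child[nxt] == -1 else None
        turn ^= 1
    return Agent(parent1.net, child, validate=False)


def mutation_count(n_nodes: int, stagnation: int, horizon: int) -> int:
    """Self-adaptive number of digits to mutate.

    Grows with network size and with the agent's stagnation:
    ``min(N, max(1, ceil((l/R)·log2(N+1))))`` — at least one digit, never
    more than N, and e.g. 2 digits for an 8-node network stuck for half
    its horizon.
    """
    if n_nodes < 1:
        raise ValueError("network size must be positive")
    frac = stagnation / horizon if horizon > 0 else 1.0
    return min(n_nodes, max(1, math.ceil(frac * math.log2(n_nodes + 1))))


def mutate(agent: Agent, n: int, rng) -> Agent:
    """Re-point ``n`` distinct uniformly chosen nodes within their own
    feasible sets ``(Γ(i) ∪ {i}) \\ {a_i}``; the candidate stays feasible."""
    size = len(agent)
    if n > size:
        raise ValueError("cannot mutate more digits than the encoding length")
    net = agent.net
    order = net.node_order
    candidate = agent.copy()
    remaining = list(range(size))
    for _ in range(n):
        pos = remaining.pop(int(rng.integers(len(remaining))))
        options = sorted(net.index(j) for j in net.neighbors(order[pos]))
        options.append(pos)
        options = sorted(set(options) - {int(agent.assignment[pos])})
        if options:
            candidate.replace(pos, options[int(rng.integers(len(options)))])
    return candidate


@dataclass
class EvolutionResult:
    """Outcome of an evolutionary run."""

    best: Agent
    trace: list[float] = field(default_factory=list)
    iterations: int = 0


def evolve(
    net: PPINetwork,
    ann: AnnotationMap | None,
    params: Params,
    rng: np.random.Generator | None = None,
    table: StrengthTable | None = None,
) -> EvolutionResult:
    """Run the full multi-agent evolution and return the best agent seen.

    M agents are built by strength-guided random walks and placed on the
    torus in random order; each iteration sweeps the cells in row-major
    order applying competition, crossover and mutation.  The run stops when
    the global best energy has not improved for R consecutive iterations,
    or at ``max_iter``.  With the same seed and inputs the run is
    bit-reproducible.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    if table is None:
        table = build_strength_table(net, ann, epsilon=params.epsilon)
    m = params.m
    construct_rng, place_rng, ops_rng = rng.spawn(3)

    agents = [construct_agent(net, table, construct_rng) for _ in range(params.M)]
    placement = place_rng.permutation(params.M)
    grid: list[list[Agent]] = [
        [agents[placement[r * m + c]] for c in range(m)] for r in range(m)
    ]
    stagnation = np.zeros((m, m), dtype=np.int64)

    def argbest_neighbor(r: int, c: int) -> tuple[int, int]:
        # ties by lowest (row, col); lattice_neighbors returns sorted cells
        best_pos, best_e = None, -np.inf
        for (u, v) in lattice_neighbors(m, r + 1, c + 1):
            e = grid[u - 1][v - 1].energy
            if e > best_e:
                best_pos, best_e = (u - 1, v - 1), e
        return best_pos

    best = max(agents, key=lambda a: a.energy).copy()
    trace: list[float] = []
    stale = 0
    n_nodes = net.num_nodes
    it = 0
    while it < params.max_iter:
        it += 1
        for r in range(m):
            for c in range(m):
                cell = grid[r][c]
                e_before = cell.energy
                br, bc = argbest_neighbor(r, c)
                cell = competition(cell, grid[br][bc], table, params.p_o, ops_rng)
                if ops_rng.random() < params.p_c:
                    nbrs = lattice_neighbors(m, r + 1, c + 1)
                    pu, pv = nbrs[int(ops_rng.integers(len(nbrs)))]
                    partner = grid[pu - 1][pv - 1]
                    c1 = crossover_alternating_link(cell, partner, ops_rng)
                    c2 = crossover_alternating_chunk(cell, partner, ops_rng)
                    child = c1 if c1.energy >= c2.energy else c2
                    if child.energy > cell.energy:
                        cell = child
                if ops_rng.random() < params.p_m:
                    n_mut = mutation_count(n_nodes, int(stagnation[r, c]), params.R)
                    mutant = mutate(cell, n_mut, ops_rng)
                    if mutant.energy > cell.energy:
                        cell = mutant
                grid[r][c] = cell
                if cell.energy == e_before:
                    stagnation[r, c] += 1
                else:
                    stagnation[r, c] = 0
                if cell.energy > best.energy:
                    best = cell.copy()
        if trace and best.energy <= trace[-1]:
            stale += 1
        else:
            stale = 0
        trace.append(best.energy)
        if stale >= params.R:
            break
    return EvolutionResult(best=best, trace=trace, iterations=it)
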