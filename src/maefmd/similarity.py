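"""Pairwise topological / functional similarity and the gated random-walk moves.

Two proteins joined by an interaction get a combined connection strength

    strength(i, j) = s_ij + f_ij        in [0, 2]

where ``s_ij`` is the cosine similarity of the closed neighborhoods
|Γ⁺(i) ∩ Γ⁺(j)| / sqrt(|Γ⁺(i)|·|Γ⁺(j)|) and ``f_ij`` is the squared overlap
of the proteins' ontology term sets |g^i ∩ g^j|² / (|g^i|·|g^j|).  During
solution construction an agent walking on the network may only step along
edges whose combined strength reaches the threshold ε, with probability
proportional to the strength.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .io import AnnotationMap, PPINetwork

__all__ = [
    "structural_similarity",
    "functional_similarity",
    "StrengthTable",
    "build_strength_table",
    "feasible_moves",
]


def structural_similarity(net: PPINetwork, i: str, j: str) -> float:
    """Cosine similarity of the closed neighborhoods of ``i`` and ``j``.

    Equals 1 when the closed neighborhoods are identical (e.g. any adjacent
    pair of a triangle) and 0 when they share no protein.
    """
    gi = net.neighbors(i) | {i}
    gj = net.neighbors(j) | {j}
    return len(gi & gj) / math.sqrt(len(gi) * len(gj))


def functional_similarity(ann: AnnotationMap | None, i: str, j: str) -> float:
    """Squared term-set overlap |g^i ∩ g^j|² / (|g^i|·|g^j|).

    Zero whenever either protein has no annotation, so incomplete GO files
    degrade gracefully instead of erroring.
    """
    if ann is None:
        return 0.0
    gi = ann.get(i)
    gj = ann.get(j)
    if not gi or not gj:
        return 0.0
    return len(gi & gj) ** 2 / (len(gi) * len(gj))


@dataclass
class StrengthTable:
    """Combined per-edge connection strengths, computed once and shared.

    ``strength`` maps each unordered network edge to ``s_ij + f_ij``;
    ``epsilon`` is the gate a move must reach to be feasible.
    """

    strength: dict[frozenset[str], float]
    epsilon: float = 0.0
    # index-based mirror for the fast engine: node index -> (nbr indices, strengths)
    _by_index: dict[int, tuple[np.ndarray, np.ndarray]] | None = field(
        default=None, repr=False, compare=False
    )

    def lookup(self, i: str, j: str) -> float:
        return self.strength[frozenset((i, j))]

    def gated_neighbors(self, net: PPINetwork, u: int) -> tuple[np.ndarray, np.ndarray]:
        """Neighbor indices of node-index ``u`` with strength ≥ ε, plus strengths."""
        if self._by_index is None:
            by_index: dict[int, list[tuple[int, float]]] = {k: [] for k in range(net.num_nodes)}
            for pair, s in self.strength.items():
                if s < self.epsilon:
                    continue
                a, b = pair
                ia, ib = net.index(a), net.index(b)
                by_index[ia].append((ib, s))
                by_index[ib].append((ia, s))
            self._by_index = {}
            for k, lst in by_index.items():
                lst.sort()
                idx = np.array([t[0] for t in lst], dtype=np.int64)
                val = np.array([t[1] for t in lst], dtype=np.float64)
                self._by_index[k] = (idx, val)
        return self._by_index[u]


def build_strength_table(
    net: PPINetwork, ann: AnnotationMap | None = None, epsilon: float = 0.0
) -> StrengthTable:
    """Compute ``s_ij + f_ij`` for every network edge.

    Without annotations the strength reduces to the structural term alone.
    """
    if epsilon < 0:
        raise ValueError("epsilon must be non-negative")
    strength: dict[frozenset[str], float] = {}
    for a, b in net.graph.edges:
        strength[frozenset((a, b))] = structural_similarity(net, a, b) + functional_similarity(
            ann, a, b
        )
    return StrengthTable(strength=strength, epsilon=epsilon)


def feasible_moves(
    table: StrengthTable,
    net: PPINetwork,
    i: str,
    visited_in_traversal: set[str] = frozenset(),
) -> list[tuple[str, float]]:
    """Candidate next steps of the random walk from ``i`` with probabilities.

    Candidates are neighbors of ``i`` not yet visited in the current
    traversal whose combined strength reaches ε; selection probability is
    proportional to the strength.  Returns an empty list when no neighbor
    qualifies (the walk then ends with a breakpoint).
    """
    cands: list[tuple[str, float]] = []
    for j in sorted(net.neighbors(i)):
        if j in visited_in_traversal:
            continue
        s = table.lookup(i, j)
        if s >= table.epsilon:
            cands.append((j, s))
    total = sum(s for _, s in cands)
    if not cands or total == 0.0:
        return [] if not cands else [(j, 1.0 / len(cands)) for j, _ in cands]
    return [(j, s / total) for j, s in cands]
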