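"""Readers and writers for the three on-disk formats the tool touches.

A PPI network arrives as a two-column edge list (DIP/BioGRID export style),
protein annotations as a two-column protein/term TSV, and module or complex
sets as flat files with one whitespace-separated complex per line.  The
network reader performs the standard cleaning step: self-interactions are
dropped and repeated interactions collapse to a single undirected edge.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import networkx as nx
import numpy as np

__all__ = [
    "PPINetwork",
    "AnnotationMap",
    "ModuleSet",
    "ParseError",
    "read_network",
    "read_annotations",
    "read_module_set",
    "write_module_set",
]


class ParseError(ValueError):
    """A malformed line in an input file, reported with its line number."""


class PPINetwork:
    """A cleaned, undirected protein-protein interaction network.

    Wraps a :class:`networkx.Graph` and additionally fixes a deterministic
    node ordering (sorted protein identifiers) together with integer-indexed
    edge and degree arrays, which the evolutionary engine uses for fast
    modularity evaluation.
    """

    def __init__(self, edges: Iterable[tuple[str, str]], isolated: Iterable[str] = ()):
        g = nx.Graph()
        g.add_nodes_from(isolated)
        for a, b in edges:
            if a == b:
                continue
            g.add_edge(a, b)
        self.graph = g
        self.node_order: list[str] = sorted(g.nodes)
        self._index: dict[str, int] = {p: i for i, p in enumerate(self.node_order)}
        if g.number_of_edges():
            self.edge_index = np.array(
                sorted(
                    (min(self._index[a], self._index[b]), max(self._index[a], self._index[b]))
                    for a, b in g.edges
                ),
                dtype=np.int64,
            )
        else:
            self.edge_index = np.empty((0, 2), dtype=np.int64)
        self.degree_array = np.zeros(len(self.node_order), dtype=np.int64)
        for u, v in self.edge_index:
            self.degree_array[u] += 1
            self.degree_array[v] += 1

    # -- basic accessors -------------------------------------------------
    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def edges(self) -> set[frozenset[str]]:
        return {frozenset((a, b)) for a, b in self.graph.edges}

    @property
    def num_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def num_edges(self) -> int:
        return self.graph.number_of_edges()

    def neighbors(self, i: str) -> set[str]:
        """Open neighborhood Γ(i)."""
        if i not in self.graph:
            raise KeyError(f"unknown protein: {i!r}")
        return set(self.graph[i])

    def index(self, i: str) -> int:
        return self._index[i]

    def __contains__(self, i: str) -> bool:
        return i in self.graph

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"PPINetwork({self.num_nodes} proteins, {self.num_edges} interactions)"


@dataclass
class AnnotationMap:
    """Mapping protein → set of ontology term identifiers.

    Proteins absent from the mapping yield the empty set; the functional
    similarity of an unannotated protein with anything is zero.
    """

    terms: Mapping[str, frozenset[str]] = field(default_factory=dict)

    def get(self, protein: str) -> frozenset[str]:
        return self.terms.get(protein, frozenset())

    def __len__(self) -> int:
        return len(self.terms)

    def term_members(self) -> dict[str, frozenset[str]]:
        """Invert the map: term → set of proteins annotated with it."""
        out: dict[str, set[str]] = {}
        for p, ts in self.terms.items():
            for t in ts:
                out.setdefault(t, set()).add(p)
        return {t: frozenset(ps) for t, ps in out.items()}


class ModuleSet:
    """An ordered collection of non-empty protein sets with optional labels."""

    def __init__(
        self,
        modules: Iterable[Iterable[str]],
        names: Sequence[str] | None = None,
    ):
        self.modules: list[frozenset[str]] = [frozenset(m) for m in modules]
        if any(not m for m in self.modules):
            raise ValueError("modules must be non-empty")
        if names is not None and len(names) != len(self.modules):
            raise ValueError("names and modules must have the same length")
        self.names: list[str] | None = list(names) if names is not None else None

    def __len__(self) -> int:
        return len(self.modules)

    def __iter__(self) -> Iterator[frozenset[str]]:
        return iter(self.modules)

    def __getitem__(self, i: int) -> frozenset[str]:
        return self.modules[i]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ModuleSet):
            return NotImplemented
        return self.modules == other.modules and self.names == other.names

    def proteins(self) -> frozenset[str]:
        out: set[str] = set()
        for m in self.modules:
            out |= m
        return frozenset(out)

    def is_partition(self) -> bool:
        return sum(len(m) for m in self.modules) == len(self.proteins())

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"ModuleSet({len(self.modules)} modules, {len(self.proteins())} proteins)"


def _data_lines(path: str | Path) -> Iterator[tuple[int, str]]:
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            yield lineno, line


def read_network(path: str | Path) -> PPINetwork:
    """Read a tab/whitespace-separated edge list and clean it.

    The first two tokens of each non-comment line are protein identifiers;
    extra columns (weights, evidence codes) are ignored.  Self-interactions
    are dropped, and (a,b)/(b,a) duplicates collapse to one undirected edge.
    A line with a single token declares an isolated protein.
    """
    edges: list[tuple[str, str]] = []
    isolated: list[str] = []
    for lineno, line in _data_lines(path):
        toks = line.split()
        if len(toks) == 1:
            isolated.append(toks[0])
            continue
        edges.append((toks[0], toks[1]))
    return PPINetwork(edges, isolated=isolated)


def read_annotations(path: str | Path) -> AnnotationMap:
    """Read a two-column protein/term TSV into an :class:`AnnotationMap`.

    Term sets are unioned over repeated protein rows; duplicates are
    harmless (set semantics).
    """
    terms: dict[str, set[str]] = {}
    for lineno, line in _data_lines(path):
        toks = line.split()
        if len(toks) < 2:
            raise ParseError(f"{path}:{lineno}: expected 'protein<TAB>term', got {line!r}")
        terms.setdefault(toks[0], set()).add(toks[1])
    return AnnotationMap({p: frozenset(ts) for p, ts in terms.items()})


def read_module_set(path: str | Path) -> ModuleSet:
    """Read a flat complex file: one module per line, whitespace-separated.

    A leading ``name<TAB>`` label is kept when present (detected by a tab in
    the line); duplicate identifiers within a line are deduplicated.
    """
    modules: list[frozenset[str]] = []
    names: list[str] = []
    labelled = False
    for lineno, line in _data_lines(path):
        if "\t" in line:
            label, rest = line.split("\t", 1)
            members = rest.split()
            labelled = True
        else:
            label = ""
            members = line.split()
        if not members:
            warnings.warn(f"{path}:{lineno}: blank module line skipped")
            continue
        modules.append(frozenset(members))
        names.append(label)
    if not labelled:
        return ModuleSet(modules)
    return ModuleSet(modules, names=names)


def write_module_set(ms: ModuleSet, path: str | Path) -> None:
    """Write a :class:`ModuleSet` so that it round-trips through
    :func:`read_module_set` with identical membership and labels."""
    with open(path, "w", encoding="utf-8") as fh:
        for k, module in enumerate(ms.modules):
            members = " ".join(sorted(module))
            if ms.names is not None:
                fh.write(f"{ms.names[k]}\t{members}\n")
            else:
                fh.write(members + "\n")
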