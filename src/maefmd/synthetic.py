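"""Planted-partition PPI networks with consistent synthetic annotations.

The generator emulates the structure the detector exploits in real
interaction data: proteins fall into K ground-truth modules, within-module
interactions appear with probability ``p_in`` and cross-module ones with
``p_out`` (dense inside, sparse between), and every protein carries the
private term set of its module, optionally polluted with one foreign term
at a tunable noise rate.  Everything is seeded and bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from pathlib import Path

import numpy as np

from .io import AnnotationMap, ModuleSet, PPINetwork, write_module_set

__all__ = [
    "planted_partition_network",
    "synthetic_annotations",
    "SyntheticCase",
    "planted_case",
]


def _node_names(n: int) -> list[str]:
    width = max(3, len(str(n)))
    return [f"p{k:0{width}d}" for k in range(1, n + 1)]


def planted_partition_network(
    n: int, K: int, p_in: float, p_out: float, rng: np.random.Generator
) -> tuple[PPINetwork, ModuleSet]:
    """Sample a planted-partition graph and return it with its ground truth.

    Nodes are split into K blocks as evenly as possible; each within-block
    pair becomes an interaction with probability ``p_in`` and each
    cross-block pair with ``p_out``.  With p_in=1, p_out=0 the graph is a
    disjoint union of block cliques.
    """
    if not (n >= K >= 1):
        raise ValueError("need n >= K >= 1")
    if not (0.0 <= p_out <= p_in <= 1.0):
        raise ValueError("need 0 <= p_out <= p_in <= 1")
    names = _node_names(n)
    block = np.repeat(np.arange(K), np.diff(np.linspace(0, n, K + 1).astype(int)))
    edges: list[tuple[str, str]] = []
    for a, b in combinations(range(n), 2):
        p = p_in if block[a] == block[b] else p_out
        if p > 0 and rng.random() < p:
            edges.append((names[a], names[b]))
    net = PPINetwork(edges, isolated=names)
    truth = ModuleSet(
        [[names[i] for i in range(n) if block[i] == c] for c in range(K)],
        names=[f"block_{c + 1}" for c in range(K)],
    )
    return net, truth


def synthetic_annotations(
    truth: ModuleSet,
    terms_per_module: int = 3,
    noise_rate: float = 0.0,
    rng: np.random.Generator | None = None,
) -> AnnotationMap:
    """Give every protein its module's private term set, plus optional noise.

    Each ground-truth module owns ``terms_per_module`` private terms shared
    by all its members, so within-module functional similarity is 1 and
    cross-module similarity is 0 at zero noise.  With probability
    ``noise_rate`` a protein additionally receives one term drawn from a
    uniformly random other module.
    """
    if not 0.0 <= noise_rate <= 1.0:
        raise ValueError("noise_rate must lie in [0, 1]")
    if rng is None:
        rng = np.random.default_rng(0)
    k = len(truth)
    module_terms = [
        frozenset(f"T{c + 1:03d}_{t + 1}" for t in range(terms_per_module)) for c in range(k)
    ]
    terms: dict[str, frozenset[str]] = {}
    for c, module in enumerate(truth):
        for p in sorted(module):
            ts = set(module_terms[c])
            if terms_per_module > 0 and k > 1 and rng.random() < noise_rate:
                other = int(rng.integers(k - 1))
                other = other if other < c else other + 1
                foreign = sorted(module_terms[other])
                ts.add(foreign[int(rng.integers(len(foreign)))])
            if ts:
                terms[p] = frozenset(ts)
    return AnnotationMap(terms)


@dataclass
class SyntheticCase:
    """A generated study case: network, annotations and ground truth."""

    network: PPINetwork
    annotations: AnnotationMap
    truth: ModuleSet
    n: int
    K: int
    p_in: float
    p_out: float
    terms_per_module: int
    noise_rate: float
    seed: int

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Write edge-list TSV, annotation TSV and truth complex file."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "network": outdir / "network.tsv",
            "annotations": outdir / "annotations.tsv",
            "truth": outdir / "truth_complexes.txt",
        }
        with open(paths["network"], "w") as fh:
            for a, b in sorted(tuple(sorted(e)) for e in self.network.edges):
                fh.write(f"{a}\t{b}\n")
        with open(paths["annotations"], "w") as fh:
            for p in sorted(self.annotations.terms):
                for t in sorted(self.annotations.terms[p]):
                    fh.write(f"{p}\t{t}\n")
        write_module_set(self.truth, paths["truth"])
        return paths


def planted_case(
    n: int = 60,
    K: int = 6,
    p_in: float = 0.9,
    p_out: float = 0.05,
    terms_per_module: int = 3,
    noise_rate: float = 0.1,
    seed: int = 0,
) -> SyntheticCase:
    """The default study case: 6 planted modules of 10 proteins each,
    dense inside (0.9), sparse between (0.05), 10% annotation noise."""
    rng = np.random.default_rng(seed)
    net_rng, ann_rng = rng.spawn(2)
    net, truth = planted_partition_network(n, K, p_in, p_out, net_rng)
    ann = synthetic_annotations(truth, terms_per_module, noise_rate, ann_rng)
    return SyntheticCase(net, ann, truth, n, K, p_in, p_out, terms_per_module, noise_rate, seed)
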