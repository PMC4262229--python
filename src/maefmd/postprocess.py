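"""Refinement of the preliminary partition into final modules.

Two steps follow the evolutionary search: functionally close modules are
merged (greedy best pair first, while any pair exceeds the merging
threshold λ), and modules that are too small or too sparsely interconnected
(induced density below δ) are discarded.
"""

from __future__ import annotations

from dataclasses import dataclass

from .io import AnnotationMap, ModuleSet, PPINetwork
from .similarity import functional_similarity

__all__ = [
    "module_similarity",
    "merge_modules",
    "filter_modules",
    "module_density",
    "PostprocessReport",
    "postprocess",
]


def module_similarity(ms: frozenset[str], mt: frozenset[str], ann: AnnotationMap | None) -> float:
    """Symmetric best-match functional similarity between two modules.

    S(M_S, M_T) = mean over M_S of the best f_ij against M_T, plus the same
    the other way round — in [0, 2]; 0 when nothing is annotated.
    """
    if not ms or not mt:
        raise ValueError("modules must be non-empty")
    if ann is None:
        return 0.0
    fwd = sum(max(functional_similarity(ann, i, j) for j in mt) for i in ms) / len(ms)
    bwd = sum(max(functional_similarity(ann, i, j) for i in ms) for j in mt) / len(mt)
    return fwd + bwd


def merge_modules(ms: ModuleSet, ann: AnnotationMap | None, lambda_merge: float) -> ModuleSet:
    """Iteratively merge the functionally closest module pair while S > λ.

    Ties on the similarity are broken by the earliest (i, j) index pair;
    the merged module takes the earlier slot (and its label).  Disjointness
    is preserved.
    """
    modules = list(ms.modules)
    names = list(ms.names) if ms.names is not None else None
    while len(modules) > 1:
        best_pair, best_s = None, -1.0
        for i in range(len(modules)):
            for j in range(i + 1, len(modules)):
                s = module_similarity(modules[i], modules[j], ann)
                if s > best_s:
                    best_pair, best_s = (i, j), s
        if best_s <= lambda_merge:
            break
        i, j = best_pair
        modules[i] = modules[i] | modules[j]
        del modules[j]
        if names is not None:
            del names[j]
    return ModuleSet(modules, names=names)


def module_density(module: frozenset[str], net: PPINetwork) -> float:
    """Induced-subgraph density D_s = 2·e_s / (n_s·(n_s−1))."""
    n_s = len(module)
    if n_s < 2:
        return 0.0
    members = [p for p in module if p in net]
    e_s = net.graph.subgraph(members).number_of_edges()
    return 2.0 * e_s / (n_s * (n_s - 1))


def filter_modules(ms: ModuleSet, net: PPINetwork, delta_filter: float) -> ModuleSet:
    """Drop modules with fewer than two proteins or induced density < δ."""
    keep = [
        k
        for k, module in enumerate(ms.modules)
        if len(module) >= 2 and module_density(module, net) >= delta_filter
    ]
    names = [ms.names[k] for k in keep] if ms.names is not None else None
    return ModuleSet([ms.modules[k] for k in keep], names=names)


@dataclass
class PostprocessReport:
    merges_performed: int
    modules_filtered: int
    final: ModuleSet


def postprocess(
    ms: ModuleSet,
    net: PPINetwork,
    ann: AnnotationMap | None,
    lambda_merge: float,
    delta_filter: float,
) -> PostprocessReport:
    """Merge then filter, reporting how much each step changed."""
    merged = merge_modules(ms, ann, lambda_merge)
    final = filter_modules(merged, net, delta_filter)
    return PostprocessReport(
        merges_performed=len(ms) - len(merged),
        modules_filtered=len(merged) - len(final),
        final=final,
    )
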