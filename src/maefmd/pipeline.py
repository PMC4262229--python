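"""End-to-end detection: strength table → evolution → post-processing."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .agent import decode
from .evolution import EvolutionResult, Params, evolve
from .io import AnnotationMap, ModuleSet, PPINetwork
from .postprocess import PostprocessReport, postprocess
from .similarity import build_strength_table

__all__ = ["DetectionResult", "detect_modules"]


@dataclass
class DetectionResult:
    """Everything a detection run produced."""

    modules: ModuleSet
    best_energy: float
    trace: list[float]
    iterations: int
    preliminary: ModuleSet
    post: PostprocessReport


def detect_modules(
    net: PPINetwork,
    ann: AnnotationMap | None = None,
    params: Params | None = None,
    rng: np.random.Generator | None = None,
) -> DetectionResult:
    """Run the full detector on a cleaned network.

    Builds the shared connection-strength table, evolves the agent
    population until the best energy stagnates, decodes the best agent to
    preliminary modules, then merges functionally close modules (threshold
    λ) and filters small or sparse ones (threshold δ).
    """
    if params is None:
        params = Params()
    table = build_strength_table(net, ann, epsilon=params.epsilon)
    result: EvolutionResult = evolve(net, ann, params, rng=rng, table=table)
    preliminary = decode(result.best)
    post = postprocess(preliminary, net, ann, params.lambda_merge, params.delta_filter)
    return DetectionResult(
        modules=post.final,
        best_energy=result.best.energy,
        trace=result.trace,
        iterations=result.iterations,
        preliminary=preliminary,
        post=post,
    )
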