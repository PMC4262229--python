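"""Evaluation of predicted modules against a reference complex set.

Predicted and reference modules are matched by the neighborhood-affinity
score NA(p, b) = |p ∩ b|² / (|p|·|b|); NA ≥ ω (usually 0.2) counts as a
match, giving complex-wise precision/recall/F-measure.  Clustering-wise
quality uses the overlap matrix T (T_ij = |B_i ∩ P_j|): sensitivity Sn,
positive predictive value PPV and their geometric mean Acc.  Individual
modules are scored for functional homogeneity with the hypergeometric
tail p-value of their best term overlap.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.stats import hypergeom

from .io import AnnotationMap, ModuleSet, PPINetwork

__all__ = [
    "na_score",
    "complex_prediction_metrics",
    "coverage",
    "accuracy_metrics",
    "hypergeometric_pvalue",
    "matching_rate",
    "module_pvalue",
    "EvaluationReport",
    "evaluate",
]


def na_score(vp: frozenset[str] | set[str], vb: frozenset[str] | set[str]) -> float:
    """Neighborhood affinity |vp ∩ vb|² / (|vp|·|vb|), symmetric, in [0, 1]."""
    if not vp or not vb:
        raise ValueError("NA is undefined for empty protein sets")
    inter = len(set(vp) & set(vb))
    return inter * inter / (len(vp) * len(vb))


def complex_prediction_metrics(
    P: ModuleSet, B: ModuleSet, omega: float = 0.2
) -> tuple[int, int, float, float, float]:
    """Counts of matched modules and complex-wise precision/recall/F.

    N_cp = predicted modules matching at least one reference at NA ≥ ω;
    N_cb = references matched by at least one prediction.  F is the
    harmonic mean of precision and recall (0 when both vanish).
    """
    if not 0.0 < omega <= 1.0:
        raise ValueError("omega must lie in (0, 1]")
    if len(P) == 0 or len(B) == 0:
        return 0, 0, 0.0, 0.0, 0.0
    n_cp = sum(1 for p in P if any(na_score(p, b) >= omega for b in B))
    n_cb = sum(1 for b in B if any(na_score(p, b) >= omega for p in P))
    precision = n_cp / len(P)
    recall = n_cb / len(B)
    f = 2 * precision * recall / (precision + recall) if precision + recall > 0 else 0.0
    return n_cp, n_cb, precision, recall, f


def coverage(P: ModuleSet, net: PPINetwork) -> float:
    """Fraction of network proteins assigned to any predicted module."""
    if net.num_nodes == 0:
        raise ValueError("coverage is undefined for an empty network")
    return len(P.proteins() & net.nodes) / net.num_nodes


def accuracy_metrics(P: ModuleSet, B: ModuleSet) -> tuple[float, float, float]:
    """Clustering-wise sensitivity, PPV and their geometric mean Acc.

    Sn = Σ_i max_j T_ij / Σ_i |B_i|; PPV = Σ_j max_i T_ij / Σ_ij T_ij
    (0 when no overlap at all); Acc = sqrt(Sn·PPV).
    """
    if len(P) == 0 or len(B) == 0:
        return 0.0, 0.0, 0.0
    T = np.array([[len(b & p) for p in P.modules] for b in B.modules], dtype=np.float64)
    sn = T.max(axis=1).sum() / sum(len(b) for b in B.modules)
    col_total = T.sum()
    ppv = T.max(axis=0).sum() / col_total if col_total > 0 else 0.0
    return float(sn), float(ppv), float(np.sqrt(sn * ppv))


def hypergeometric_pvalue(universe: int, module_size: int, function_size: int, overlap: int) -> float:
    """P(X ≥ k) for the overlap of a size-|C| module with a size-|F| function.

    The probability that drawing |C| proteins from a universe of |V| yields
    at least ``overlap`` of the |F| function members.  Computed through the
    hypergeometric survival function (stable in log space); k = 0 gives 1.
    """
    if not (0 <= overlap <= min(module_size, function_size)):
        raise ValueError("overlap must not exceed either set size")
    if module_size > universe or function_size > universe:
        raise ValueError("set sizes cannot exceed the universe")
    return float(hypergeom.sf(overlap - 1, universe, function_size, module_size))


def matching_rate(predicted: frozenset[str] | set[str], reference: frozenset[str] | set[str]) -> float:
    """Percent of the predicted module's proteins found in the reference."""
    if not predicted:
        raise ValueError("matching rate is undefined for an empty prediction")
    return 100.0 * len(set(predicted) & set(reference)) / len(predicted)


def module_pvalue(
    module: frozenset[str], ann: AnnotationMap, universe: int
) -> tuple[float, str | None]:
    """Minimum hypergeometric p-value of the module over all annotated terms.

    Each ontology term defines a reference function (its annotated protein
    set); returns (1.0, None) when nothing overlaps.
    """
    best_p, best_term = 1.0, None
    for term, members in sorted(ann.term_members().items()):
        k = len(module & members)
        if k == 0:
            continue
        p = hypergeometric_pvalue(universe, len(module), len(members), k)
        if p < best_p:
            best_p, best_term = p, term
    return best_p, best_term


@dataclass
class ModuleRow:
    """Per-predicted-module evaluation line."""

    name: str
    size: int
    best_na: float
    best_reference: str
    matching_rate: float
    min_pvalue: float | None


@dataclass
class EvaluationReport:
    """Full evaluation of a predicted module set against a reference set."""

    n_predicted: int
    n_reference: int
    n_cp: int
    n_cb: int
    precision: float
    recall: float
    f_measure: float
    coverage: float | None
    sn: float
    ppv: float
    acc: float
    omega: float
    per_module: list[ModuleRow] = field(default_factory=list)

    def to_dict(self) -> dict:
        d = {
            k: getattr(self, k)
            for k in (
                "n_predicted", "n_reference", "n_cp", "n_cb", "precision",
                "recall", "f_measure", "coverage", "sn", "ppv", "acc", "omega",
            )
        }
        d["per_module"] = [vars(r) for r in self.per_module]
        return d

    def write_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    def write_tsv(self, path: str | Path) -> None:
        lines = ["module\tsize\tbest_na\tbest_reference\tmatching_rate\tmin_pvalue"]
        for r in self.per_module:
            pv = "" if r.min_pvalue is None else f"{r.min_pvalue:.3e}"
            lines.append(
                f"{r.name}\t{r.size}\t{r.best_na:.4f}\t{r.best_reference}"
                f"\t{r.matching_rate:.1f}\t{pv}"
            )
        Path(path).write_text("\n".join(lines) + "\n")


def evaluate(
    P: ModuleSet,
    B: ModuleSet,
    net: PPINetwork | None = None,
    ann: AnnotationMap | None = None,
    omega: float = 0.2,
    restrict_to_network: bool = False,
) -> EvaluationReport:
    """Compute every evaluation measure in one report.

    Reference proteins absent from the network are kept by default (curated
    complexes routinely contain proteins missing from an interaction
    screen); ``restrict_to_network`` intersects references with the network
    node set first.  Coverage needs the network; per-module p-values need
    annotations.
    """
    if restrict_to_network and net is not None:
        kept = [b & frozenset(net.node_order) for b in B.modules]
        pairs = [(b, i) for i, b in enumerate(kept) if b]
        B = ModuleSet(
            [b for b, _ in pairs],
            names=[B.names[i] for _, i in pairs] if B.names is not None else None,
        )
    n_cp, n_cb, precision, recall, f = complex_prediction_metrics(P, B, omega)
    sn, ppv, acc = accuracy_metrics(P, B)
    cov = coverage(P, net) if net is not None else None
    rows: list[ModuleRow] = []
    universe = net.num_nodes if net is not None else len(P.proteins() | B.proteins())
    for k, p in enumerate(P.modules):
        name = P.names[k] if P.names is not None else f"module_{k + 1}"
        if len(B):
            best_idx = max(range(len(B)), key=lambda i: na_score(p, B[i]))
            best_na = na_score(p, B[best_idx])
            ref_name = (
                B.names[best_idx] if B.names is not None else f"reference_{best_idx + 1}"
            )
            mr = matching_rate(p, B[best_idx])
        else:
            best_na, ref_name, mr = 0.0, "", 0.0
        pv = module_pvalue(p, ann, universe)[0] if ann is not None else None
        rows.append(ModuleRow(name, len(p), best_na, ref_name, mr, pv))
    return EvaluationReport(
        n_predicted=len(P), n_reference=len(B), n_cp=n_cp, n_cb=n_cb,
        precision=precision, recall=recall, f_measure=f, coverage=cov,
        sn=sn, ppv=ppv, acc=acc, omega=omega, per_module=rows,
    )
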