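"""Ontology-derived constraints and multi-source penalty-weight fusion.

Term similarity follows the aggregate-information-content scheme: each term
carries an information content IC(t) = -log p(t) (nats), a semantic weight
SW(t) = 1 / (1 + exp(-1/IC(t))) and a semantic value SV(t) that aggregates
SW over the term's ancestor closure. Two terms are similar to the extent
that their ancestor closures share semantic weight; two genes are similar
through a best-match average over their annotation sets. Gene pairs with
similarity above / below a pair of thresholds (default 0.9 / 0.1) yield
ontology must-link / cannot-link constraints.

Fusion assigns each expression-derived constraint a signed violation
penalty modulated by the ontology: agreement between the two sources
strengthens the weight to +-(1 + theta), an ontology that stays silent
weakens it to +-(1 - theta), and outright disagreement marks the pair
contradictory — it is deleted from both constraint sets.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .io import (
    AnnotationMap,
    ConstraintRecord,
    ConstraintSet,
    OntologyGraph,
    _canonical_pair,
)

__all__ = [
    "TermSemantics",
    "PenaltyWeightMatrix",
    "term_semantics",
    "sim_aic",
    "gene_similarity_go",
    "generate_go_constraints",
    "fuse_weights",
]


class UnannotatedGeneError(KeyError):
    """Functional similarity was requested for a gene with no annotations."""


@dataclass
class TermSemantics:
    """Per-term IC / SW / SV and cached ancestor closures."""

    ic: dict[str, float]
    sw: dict[str, float]
    sv: dict[str, float]
    ancestors: dict[str, frozenset[str]]

    def require(self, term: str) -> None:
        if term not in self.sw:
            raise KeyError(f"term without semantics (no frequency?): {term}")


def _semantic_weight(ic: float) -> float:
    # continuity: SW -> 1 as IC -> 0+ (the root), SW -> 0.5 as IC -> inf
    if ic == 0.0:
        return 1.0
    return 1.0 / (1.0 + math.exp(-1.0 / ic))


def term_semantics(ontology: OntologyGraph) -> TermSemantics:
    """Compute IC, SW, SV and ancestor closures for every annotated term."""
    if not ontology.term_frequency:
        raise ValueError("ontology has no term frequencies; load annotations first")
    ic: dict[str, float] = {}
    sw: dict[str, float] = {}
    sv: dict[str, float] = {}
    ancestors: dict[str, frozenset[str]] = {}
    for term, p in ontology.term_frequency.items():
        if not 0.0 < p <= 1.0:
            raise ValueError(f"term frequency p({term}) = {p} outside (0, 1]")
        ic[term] = -math.log(p)
        sw[term] = _semantic_weight(ic[term])
    for term in ic:
        anc = frozenset(t for t in ontology.ancestors(term) if t in sw)
        ancestors[term] = anc
        sv[term] = sum(sw[t] for t in anc)
    return TermSemantics(ic=ic, sw=sw, sv=sv, ancestors=ancestors)


def sim_aic(t1: str, t2: str, sem: TermSemantics) -> float:
    """Aggregate-information-content similarity of two terms, in [0, 1]."""
    sem.require(t1)
    sem.require(t2)
    shared = sem.ancestors[t1] & sem.ancestors[t2]
    if not shared:
        return 0.0
    return 2.0 * sum(sem.sw[t] for t in shared) / (sem.sv[t1] + sem.sv[t2])


def gene_similarity_go(
    g1: str, g2: str, ann: AnnotationMap, sem: TermSemantics
) -> float:
    """Best-match-average functional similarity of two annotated genes."""
    terms1 = ann.get(g1)
    terms2 = ann.get(g2)
    if not terms1:
        raise UnannotatedGeneError(f"gene {g1!r} has no annotations")
    if not terms2:
        raise UnannotatedGeneError(f"gene {g2!r} has no annotations")
    best_vs_1 = sum(max(sim_aic(t1, t2, sem) for t1 in terms1) for t2 in terms2)
    best_vs_2 = sum(max(sim_aic(t2, t1, sem) for t2 in terms2) for t1 in terms1)
    return (best_vs_1 + best_vs_2) / (len(terms1) + len(terms2))


def generate_go_constraints(
    ann: AnnotationMap,
    sem: TermSemantics,
    hi: float = 0.9,
    lo: float = 0.1,
) -> ConstraintSet:
    """Threshold pairwise functional similarity into ML/CL constraints.

    Strict inequalities: similarity > ``hi`` gives a must-link,
    similarity < ``lo`` a cannot-link. Unannotated genes contribute nothing.
    """
    if not 0.0 <= lo < hi <= 1.0:
        raise ValueError(f"need 0 <= lo < hi <= 1, got lo={lo}, hi={hi}")
    out = ConstraintSet()
    annotated = sorted(g for g, terms in ann.items() if terms)
    for g1, g2 in itertools.combinations(annotated, 2):
        sim = gene_similarity_go(g1, g2, ann, sem)
        if sim > hi:
            out.add(ConstraintRecord(g1, g2, "ML", "ontology"))
        elif sim < lo:
            out.add(ConstraintRecord(g1, g2, "CL", "ontology"))
    return out


@dataclass
class PenaltyWeightMatrix:
    """Sparse symmetric constraint-violation weights over gene pairs.

    ``weights`` maps a canonical gene pair to its fused weight; absent
    pairs (and the diagonal) are zero. Nonzero values lie in
    {1 - theta, -(1 - theta), 1 + theta, -(1 + theta)}.
    """

    theta: float
    weights: dict[tuple[str, str], float] = field(default_factory=dict)

    def get(self, a: str, b: str) -> float:
        if a == b:
            return 0.0
        return self.weights.get(_canonical_pair(a, b), 0.0)

    def to_dense(self, gene_ids: list[str]) -> np.ndarray:
        index = {g: i for i, g in enumerate(gene_ids)}
        w = np.zeros((len(gene_ids), len(gene_ids)))
        for (a, b), val in self.weights.items():
            if a in index and b in index:
                w[index[a], index[b]] = w[index[b], index[a]] = val
        return w


def fuse_weights(
    omega: ConstraintSet,
    omega_star: ConstraintSet,
    theta: float,
    gene_ids: list[str] | None = None,
) -> tuple[PenaltyWeightMatrix, ConstraintSet, ConstraintSet]:
    """Fuse expression and ontology constraints into penalty weights.

    Returns the weight matrix plus both constraint sets with contradictory
    pairs (ML in one source, CL in the other) removed. Only pairs present
    in the expression set carry nonzero weight; ontology-only pairs remain
    selectable as constraints but fall under the zero branch.
    """
    if theta <= 0:
        raise ValueError("theta must be positive")
    if theta >= 1:
        warnings.warn(
            f"theta = {theta} >= 1 flips the sign of single-source weights",
            stacklevel=2,
        )
    known = set(gene_ids) if gene_ids is not None else None
    if known is not None:
        for rec in itertools.chain(omega, omega_star):
            if rec.gene_a not in known or rec.gene_b not in known:
                raise KeyError(f"constraint on unknown gene: {rec}")

    ml = omega.pairs(kind="ML")
    cl = omega.pairs(kind="CL")
    ml_star = omega_star.pairs(kind="ML")
    cl_star = omega_star.pairs(kind="CL")

    contradictory = (ml & cl_star) | (cl & ml_star)

    pruned_omega = ConstraintSet(r for r in omega if r.pair not in contradictory)
    pruned_star = ConstraintSet(r for r in omega_star if r.pair not in contradictory)

    weights: dict[tuple[str, str], float] = {}
    for pair in ml - contradictory:
        weights[pair] = 1.0 + theta if pair in ml_star else 1.0 - theta
    for pair in cl - contradictory:
        weights[pair] = -(1.0 + theta) if pair in cl_star else -(1.0 - theta)

    return PenaltyWeightMatrix(theta=theta, weights=weights), pruned_omega, pruned_star
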