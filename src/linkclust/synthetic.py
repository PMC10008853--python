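"""Synthetic ground-truthed inputs for every pipeline stage.

The generator emulates the structure the method exploits in real
transcriptomic data: genes fall into k co-expression clusters (isotropic
Gaussian blobs with controllable separation), functional annotation is
concordant with co-expression (each cluster owns one branch of a small
ontology and its genes are annotated within that branch), and pairwise
constraints may be corrupted at a controllable rate to model noisy
supervision. Everything is reproducible from a single seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy.spatial.distance import pdist

from .io import (
    AnnotationMap,
    ConstraintRecord,
    ConstraintSet,
    ExpressionMatrix,
    OntologyGraph,
    compute_term_frequencies,
    normalize_minmax,
)

__all__ = [
    "SyntheticSpec",
    "make_expression",
    "make_ontology",
    "inject_constraint_noise",
]


@dataclass
class SyntheticSpec:
    """Parameters of one synthetic study condition."""

    n: int = 200  # genes
    d: int = 10  # features (samples / time points)
    k: int = 4  # ground-truth clusters
    separation: float = 6.0  # min pairwise mean distance, in units of sigma
    sigma: float = 1.0  # within-cluster standard deviation
    annotation_noise: float = 0.0  # fraction of genes annotated to a wrong branch
    constraint_noise: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < self.k:
            raise ValueError("need n >= k")
        if self.separation <= 0:
            raise ValueError("separation must be positive")
        for name in ("annotation_noise", "constraint_noise"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")


def make_expression(spec: SyntheticSpec) -> tuple[ExpressionMatrix, np.ndarray]:
    """k isotropic Gaussian blobs at a controlled degree of separation.

    Separation follows the c-separation convention for Gaussian mixtures:
    the minimum pairwise distance between cluster means is
    ``separation * sigma * sqrt(d)``, i.e. separation is measured against
    the within-cluster RMS radius, not the per-coordinate sigma — in high
    dimension that radius (sigma * sqrt(d)) is the scale on which blobs
    overlap. Cluster means are drawn uniformly and rescaled to hit the
    requested minimum exactly; sizes are balanced (remainder spread over
    the first clusters). The matrix is min-max normalized per feature and
    ground-truth labels are returned alongside.
    """
    rng = np.random.default_rng(spec.seed)
    means = rng.uniform(0.0, 1.0, size=(spec.k, spec.d))
    while pdist(means).min() == 0.0:  # pragma: no cover - measure-zero
        means = rng.uniform(0.0, 1.0, size=(spec.k, spec.d))
    means *= spec.separation * spec.sigma * np.sqrt(spec.d) / pdist(means).min()

    base, extra = divmod(spec.n, spec.k)
    sizes = [base + (1 if c < extra else 0) for c in range(spec.k)]
    labels = np.repeat(np.arange(spec.k), sizes)
    values = means[labels] + spec.sigma * rng.standard_normal((spec.n, spec.d))
    m = ExpressionMatrix(
        gene_ids=[f"g{i:04d}" for i in range(spec.n)], values=values
    )
    return normalize_minmax(m), labels


def make_ontology(
    spec: SyntheticSpec, labels: np.ndarray
) -> tuple[OntologyGraph, AnnotationMap]:
    """A k-branch ontology whose annotations mirror the cluster labels.

    Each cluster owns a branch: a branch head under the root with four
    descendant terms (two mid-level terms, each with one leaf). Every gene
    is annotated to 2-4 terms of its own branch, except an
    ``annotation_noise`` fraction annotated within another cluster's
    branch. Term frequencies (true-path rule) are computed before return.
    """
    rng = np.random.default_rng(spec.seed + 1)
    graph = nx.DiGraph()
    root = "T:ROOT"
    graph.add_node(root)
    branch_terms: list[list[str]] = []
    for c in range(spec.k):
        head = f"T:{c}:HEAD"
        mids = [f"T:{c}:M{i}" for i in range(2)]
        leaves = [f"T:{c}:L{i}" for i in range(2)]
        graph.add_edge(head, root)
        for mid, leaf in zip(mids, leaves):
            graph.add_edge(mid, head)
            graph.add_edge(leaf, mid)
        branch_terms.append([head, *mids, *leaves])
    ontology = OntologyGraph(graph=graph)

    n = len(labels)
    n_noisy = round(spec.annotation_noise * n)
    noisy = set(rng.choice(n, size=n_noisy, replace=False).tolist()) if n_noisy else set()
    mapping: AnnotationMap = {}
    for i, lab in enumerate(labels):
        branch = int(lab)
        if i in noisy and spec.k > 1:
            others = [c for c in range(spec.k) if c != branch]
            branch = int(rng.choice(others))
        terms = branch_terms[branch]
        n_ann = int(rng.integers(2, 5))  # 2-4 terms
        chosen = rng.choice(len(terms), size=min(n_ann, len(terms)), replace=False)
        mapping[f"g{i:04d}"] = {terms[j] for j in chosen}
    compute_term_frequencies(mapping, ontology)
    return ontology, mapping


def inject_constraint_noise(
    cs: ConstraintSet,
    labels: np.ndarray,
    gene_ids: list[str],
    rate: float,
    rng: np.random.Generator,
) -> ConstraintSet:
    """Replace a ``rate`` fraction of constraints with label-inconsistent ones.

    Replacements keep the original kind: a noisy must-link spans two
    ground-truth clusters, a noisy cannot-link stays within one. The number
    replaced is exactly round(rate * |cs|).
    """
    if not 0.0 <= rate <= 1.0:
        raise ValueError("rate must be in [0, 1]")
    records = sorted(cs)
    n_replace = round(rate * len(records))
    if n_replace == 0:
        return ConstraintSet(records)
    label_of = {g: int(l) for g, l in zip(gene_ids, labels)}
    victims = set(rng.choice(len(records), size=n_replace, replace=False).tolist())
    existing = {r.pair for r in records}
    out = []
    for idx, rec in enumerate(records):
        if idx not in victims:
            out.append(rec)
            continue
        for _ in range(10_000):
            i, j = rng.choice(len(gene_ids), size=2, replace=False)
            a, b = gene_ids[i], gene_ids[j]
            same = label_of[a] == label_of[b]
            # inconsistent: ML across clusters, CL within one
            if (rec.kind == "ML" and not same) or (rec.kind == "CL" and same):
                candidate = ConstraintRecord(a, b, rec.kind, rec.source)
                if candidate.pair not in existing:
                    existing.add(candidate.pair)
                    out.append(candidate)
                    break
        else:  # pragma: no cover - only on pathological label structure
            raise RuntimeError("could not find a label-inconsistent replacement pair")
    return ConstraintSet(out)
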