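"""Internal (silhouette) and external (adjusted Rand) cluster validation.

The silhouette index doubles as the model-selection rule: the final
solution reported from a Pareto front is the member whose crisp labels
maximize the silhouette, with ties broken toward lower Xie-Beni and then
lower penalized cost.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import adjusted_rand_score, silhouette_samples

from .fuzzy import crisp_assignment
from .io import ExpressionMatrix

__all__ = [
    "ClusteringResult",
    "silhouette_index",
    "select_final_solution",
    "adjusted_rand",
]


@dataclass
class ClusteringResult:
    labels: np.ndarray
    si: float
    widths: np.ndarray
    solution_id: int = 0
    fitness: tuple[float, float] | None = None


def silhouette_index(m: ExpressionMatrix, labels: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean silhouette width over genes, plain Euclidean distances.

    Per-gene width is (b - a) / max(a, b) with a the mean distance to
    co-cluster genes and b the smallest mean distance to another cluster;
    singleton clusters get width 0.
    """
    labels = np.asarray(labels)
    if len(labels) != m.n:
        raise ValueError("labels length does not match the expression matrix")
    if len(np.unique(labels)) < 2:
        raise ValueError("silhouette needs at least 2 non-empty clusters")
    if len(np.unique(labels)) == m.n:
        # all clusters are singletons; every width is 0 by convention
        return 0.0, np.zeros(m.n)
    widths = silhouette_samples(m.values, labels, metric="euclidean")
    return float(widths.mean()), widths


def select_final_solution(front: list, m: ExpressionMatrix) -> ClusteringResult:
    """Pick the Pareto-front member with the best silhouette.

    Front members whose crisp labels collapse to a single cluster are
    silhouette-undefined and rank below every valid member.
    """
    if not front:
        raise ValueError("empty Pareto front")
    best: ClusteringResult | None = None
    best_key: tuple[float, float, float] | None = None
    for sid, ind in enumerate(front):
        labels = crisp_assignment(ind.memberships)
        try:
            si, widths = silhouette_index(m, labels)
        except ValueError:
            si, widths = -np.inf, np.full(m.n, -np.inf)
        xb, jp = ind.fitness
        key = (-si, xb, jp)  # max SI, then min XB, then min J_P
        if best_key is None or key < best_key:
            best_key = key
            best = ClusteringResult(
                labels=labels, si=float(si), widths=widths, solution_id=sid, fitness=ind.fitness
            )
    assert best is not None
    return best


def adjusted_rand(labels_a: np.ndarray, labels_b: np.ndarray) -> float:
    """Adjusted Rand index between two labelings of the same genes."""
    labels_a = np.asarray(labels_a)
    labels_b = np.asarray(labels_b)
    if labels_a.shape != labels_b.shape:
        raise ValueError("labelings differ in length")
    return float(adjusted_rand_score(labels_a, labels_b))
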