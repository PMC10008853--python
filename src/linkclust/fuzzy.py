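"""Clustering objectives and the constrained fuzzy membership update.

The partition model is a quadratic-regularized fuzzy c-means with a
constraint-violation penalty. For prototypes V (k x d) and memberships
U (n x k), the update is

    u_ic = 1/k + (1/eta) * u^Q_ic + beta * u^P_ic

where u^Q_ic = (1/k) sum_f (||x_i - v_f||^2 - ||x_i - v_c||^2) pulls the
membership toward near prototypes and u^P_ic propagates membership along
(signed) constraint weights w_ij. Both correction terms sum to zero over
clusters, so rows of U stay normalized analytically; memberships are NOT
clipped to [0, 1] (the quadratic regularizer admits signed values for
small eta) and crisp labels are taken by argmax. u^P depends on U itself,
so the update is iterated as a fixed point starting from u^P = 0.

Fitness is the pair (XB, J_P): the Xie-Beni validity index (compactness /
minimal prototype separation) and the penalized c-means cost.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy.spatial.distance import cdist

from .io import ExpressionMatrix

__all__ = [
    "update_memberships",
    "recompute_prototypes",
    "objective_xb",
    "objective_jp",
    "crisp_assignment",
]

logger = logging.getLogger(__name__)

WeightTriples = list[tuple[int, int, float]]  # (i, j, w_ij) with i < j, symmetric


def _sq_dists(m: ExpressionMatrix, V: np.ndarray) -> np.ndarray:
    return cdist(m.values, np.atleast_2d(V), metric="sqeuclidean")


def _penalty_product(W: WeightTriples, U: np.ndarray) -> np.ndarray:
    """(W @ U) for the sparse symmetric weight triples."""
    out = np.zeros_like(U)
    for i, j, w in W:
        out[i] += w * U[j]
        out[j] += w * U[i]
    return out


def update_memberships(
    m: ExpressionMatrix,
    V: np.ndarray,
    W: WeightTriples,
    eta: float,
    beta: float,
    k: int,
    passes: int = 10,
    tol: float = 1e-6,
) -> np.ndarray:
    """Fixed-point membership update under prototypes V and weights W."""
    if k < 1:
        raise ValueError("k must be >= 1")
    n = m.n
    d2 = _sq_dists(m, V)  # (n, k)
    # u^Q_ic = mean_f d_if - d_ic ; rows sum to zero by construction
    u_q = d2.mean(axis=1, keepdims=True) - d2
    U = 1.0 / k + (1.0 / eta) * u_q  # u^P = 0 initialization
    if not W or beta == 0.0:
        return U
    for _ in range(passes):
        wu = _penalty_product(W, U)
        u_p = wu - wu.mean(axis=1, keepdims=True)
        U_new = 1.0 / k + (1.0 / eta) * u_q + beta * u_p
        if np.abs(U_new - U).max() < tol:
            U = U_new
            break
        U = U_new
    return U


def recompute_prototypes(
    U: np.ndarray, m: ExpressionMatrix, incumbent: np.ndarray | None = None
) -> np.ndarray:
    """Membership-weighted means v_c = sum_i u_ic x_i / sum_i u_ic in [0, 1].

    A cluster with (near-)zero membership mass keeps its incumbent
    prototype when one is supplied.
    """
    mass = U.sum(axis=0)  # (k,)
    k = U.shape[1]
    V = np.empty((k, m.d))
    for c in range(k):
        if abs(mass[c]) < 1e-12:
            if incumbent is None:
                raise ZeroDivisionError(f"cluster {c} has zero membership mass")
            logger.info("cluster %d has zero membership mass; keeping prototype", c)
            V[c] = incumbent[c]
        else:
            V[c] = U[:, c] @ m.values / mass[c]
    return np.clip(V, 0.0, 1.0)


def objective_xb(U: np.ndarray, V: np.ndarray, m: ExpressionMatrix) -> float:
    """Xie-Beni index; +inf when two prototypes coincide (worst fitness)."""
    k = V.shape[0]
    if k < 2:
        raise ValueError("XB needs k >= 2")
    d2 = _sq_dists(m, V)
    sep = cdist(V, V, metric="sqeuclidean")
    np.fill_diagonal(sep, np.inf)
    min_sep = sep.min()
    if min_sep == 0.0:
        return np.inf
    return float((U**2 * d2).sum() / (m.n * min_sep))


def objective_jp(
    U: np.ndarray,
    V: np.ndarray,
    m: ExpressionMatrix,
    W: WeightTriples,
    eta: float,
    beta: float,
) -> float:
    """Penalized quadratic-regularized c-means cost."""
    d2 = _sq_dists(m, V)
    cost = float((U * d2).sum() + (eta / 2.0) * (U**2).sum())
    if W and beta != 0.0:
        # full double sum counts each symmetric pair twice
        penalty = sum(w * float(U[i] @ U[j]) for i, j, w in W)
        cost -= beta * penalty
    return cost


def crisp_assignment(U: np.ndarray) -> np.ndarray:
    """Hard labels by argmax membership; ties go to the lowest cluster index."""
    if not np.isfinite(U).all():
        raise ValueError("memberships must be finite")
    return U.argmax(axis=1)
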