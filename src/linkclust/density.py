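"""Density tracking: mine ML/CL constraints from the expression matrix alone.

Each gene gets a density (inverse of the radius of its b-nearest-neighbour
ball). Following, from each gene, the closest strictly-denser neighbour
within its neighbourhood traces a *density chain* ending at a local density
maximum; chains that merge share an endpoint and define *density groups*
(proto-clusters). Genes whose neighbourhoods mix groups and whose density
is low relative to their chain endpoint score high *impurity* — they sit on
cluster boundaries. Constraints are then mined from three sources of
structure: boundary genes paired with their nearest out-group neighbour
(cannot-link), boundary genes paired with their chain successor
(must-link), and strided walks along high-centrality chains, the cluster
"skeletons" (must-link).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import squareform, pdist

from .io import ConstraintRecord, ConstraintSet, ExpressionMatrix

__all__ = [
    "DensityModel",
    "compute_density",
    "fit_density_model",
    "generate_expression_constraints",
]


@dataclass
class DensityModel:
    """All per-gene density-tracking state for one expression matrix."""

    b: int
    densities: np.ndarray  # (n,) positive
    neighbor_lists: np.ndarray  # (n, b) int indices of the b nearest genes
    successors: np.ndarray  # (n,) int, -1 for chain endpoints
    chains: list[list[int]]  # chains[i] = i -> ... -> endpoint
    endpoints: np.ndarray  # (n,) int, terminal gene of chains[i]
    groups: np.ndarray  # (n,) int group ids (0-based, contiguous)
    centrality: np.ndarray  # (n,) int, appearances across all n chains
    chain_centrality: np.ndarray  # (n,) int, sum of centrality over chains[i]
    impurities: np.ndarray  # (n,) in [0, 1]
    distances: np.ndarray  # (n, n) condensed-to-square Euclidean distances

    @property
    def n_groups(self) -> int:
        return int(self.groups.max()) + 1 if self.groups.size else 0


def _pairwise(m: ExpressionMatrix) -> np.ndarray:
    return squareform(pdist(m.values, metric="euclidean"))


def compute_density(
    m: ExpressionMatrix, b: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-gene density 1 / max_{x_j in N_b(x_i)} ||x_i - x_j||.

    Returns (densities, neighbor_lists, full distance matrix). Neighbour
    ties are broken by lowest gene index so results are deterministic.
    """
    n = m.n
    if not 1 <= b <= n - 1:
        raise ValueError(f"need 1 <= b <= n-1, got b={b}, n={n}")
    dist = _pairwise(m)
    dup = np.argwhere(np.triu(dist == 0, k=1))
    if len(dup):
        i, j = dup[0]
        raise ValueError(
            f"coincident genes {m.gene_ids[i]!r} and {m.gene_ids[j]!r}: "
            "density is undefined for duplicate points"
        )
    # argsort on (distance, index); self is at distance 0 hence first
    order = np.argsort(dist, axis=1, kind="stable")
    neighbor_lists = order[:, 1 : b + 1]
    radii = dist[np.arange(n)[:, None], neighbor_lists].max(axis=1)
    return 1.0 / radii, neighbor_lists, dist


def fit_density_model(m: ExpressionMatrix, b: int) -> DensityModel:
    """Compute densities, chains, groups, centrality and impurity in one pass."""
    densities, neighbor_lists, dist = compute_density(m, b)
    n = m.n

    # chain successor: closest strictly-denser gene within the b-neighbourhood
    successors = np.full(n, -1, dtype=int)
    for i in range(n):
        nb = neighbor_lists[i]
        denser = nb[densities[nb] > densities[i]]
        if len(denser):
            successors[i] = denser[np.argmin(dist[i, denser])]  # stable: argmin -> lowest index on ties

    chains: list[list[int]] = []
    endpoints = np.empty(n, dtype=int)
    for i in range(n):
        chain = [i]
        while successors[chain[-1]] != -1:
            chain.append(successors[chain[-1]])
        chains.append(chain)
        endpoints[i] = chain[-1]

    # chains merging anywhere share their suffix, hence their endpoint:
    # grouping by endpoint equals connected components of the successor forest
    groups = np.empty(n, dtype=int)
    group_of_endpoint: dict[int, int] = {}
    for i in range(n):
        e = int(endpoints[i])
        if e not in group_of_endpoint:
            group_of_endpoint[e] = len(group_of_endpoint)
        groups[i] = group_of_endpoint[e]

    # centrality(x) = number of chains containing x = size of x's subtree in
    # the successor forest (every gene's own chain counts, incl. length-1)
    centrality = np.ones(n, dtype=int)
    for i in np.argsort(densities, kind="stable"):  # children before parents
        if successors[i] != -1:
            centrality[successors[i]] += centrality[i]
    chain_centrality = np.array([centrality[c].sum() for c in chains])

    model = DensityModel(
        b=b,
        densities=densities,
        neighbor_lists=neighbor_lists,
        successors=successors,
        chains=chains,
        endpoints=endpoints,
        groups=groups,
        centrality=centrality,
        chain_centrality=chain_centrality,
        impurities=np.empty(n),
        distances=dist,
    )
    model.impurities = compute_impurity(model)
    return model


def compute_impurity(model: DensityModel) -> np.ndarray:
    """Boundary score: neighbourhood group Gini x relative density deficit.

    Over S = {x_i} u N_b(x_i) (size b + 1) the Gini term 1 - sum_g p_g^2
    measures group mixing; it is damped by 1 - Density(x_i)/Density(x_e)
    so chain endpoints (local density maxima) are pure. Clamped to [0, 1].
    """
    n = len(model.densities)
    b = model.b
    impurities = np.empty(n)
    for i in range(n):
        members = np.concatenate(([i], model.neighbor_lists[i]))
        _, counts = np.unique(model.groups[members], return_counts=True)
        gini = 1.0 - np.sum((counts / (b + 1)) ** 2)
        deficit = 1.0 - model.densities[i] / model.densities[model.endpoints[i]]
        impurities[i] = gini * deficit
    return np.clip(impurities, 0.0, 1.0)


def _impurity_order(model: DensityModel) -> np.ndarray:
    # descending impurity, ties broken by lowest gene index
    return np.lexsort((np.arange(len(model.impurities)), -model.impurities))


def generate_expression_constraints(
    model: DensityModel,
    m: ExpressionMatrix,
    epsilon: float = 0.8,
    n_cl: int | None = None,
    n_ml: int | None = None,
    skeleton_stride: int = 2,
) -> ConstraintSet:
    """Mine the expression-derived constraint set from a fitted density model.

    Cannot-links pair high-impurity genes with their nearest out-group
    neighbour. Must-links pair high-impurity genes with their chain
    successor when the successor keeps at least ``epsilon`` of the endpoint
    density, then add strided skeleton pairs along chains in descending
    chain centrality. Quotas default to max(10, n // 20) per kind.
    """
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    if skeleton_stride < 1:
        raise ValueError("skeleton_stride must be >= 1")
    n = m.n
    if n_cl is None:
        n_cl = max(10, n // 20)
    if n_ml is None:
        n_ml = max(10, n // 20)
    if n_cl < 0 or n_ml < 0:
        raise ValueError("constraint quotas must be non-negative")

    ids = m.gene_ids
    out = ConstraintSet()
    cl_pairs: set[tuple[int, int]] = set()
    ml_pairs: set[tuple[int, int]] = set()

    def canon(i: int, j: int) -> tuple[int, int]:
        return (i, j) if i < j else (j, i)

    # boundary cannot-links: nearest neighbour outside the gene's own group
    if model.n_groups < 2:
        if n_cl > 0:
            warnings.warn(
                "only one density group present: cannot-link set is empty",
                stacklevel=2,
            )
    else:
        for i in _impurity_order(model):
            if len(cl_pairs) >= n_cl:
                break
            outside = np.flatnonzero(model.groups != model.groups[i])
            j = outside[np.argmin(model.distances[i, outside])]
            cl_pairs.add(canon(int(i), int(j)))

    # boundary must-links: chain successor, subject to the density drop rate
    endpoint_density = model.densities[model.endpoints]
    for i in _impurity_order(model):
        if len(ml_pairs) >= n_ml:
            break
        j = model.successors[i]
        if j == -1:
            continue
        if model.densities[j] >= epsilon * endpoint_density[i]:
            pair = canon(int(i), int(j))
            if pair not in cl_pairs:
                ml_pairs.add(pair)

    # skeleton must-links: strided walk along chains, central chains first
    chain_order = np.lexsort((np.arange(n), -model.chain_centrality))
    for ci in chain_order:
        if len(ml_pairs) >= n_ml:
            break
        chain = model.chains[ci]
        for start in range(0, len(chain) - skeleton_stride, skeleton_stride):
            pair = canon(chain[start], chain[start + skeleton_stride])
            if pair not in cl_pairs:
                ml_pairs.add(pair)
            if len(ml_pairs) >= n_ml:
                break

    for i, j in sorted(cl_pairs):
        out.add(ConstraintRecord(ids[i], ids[j], "CL", "expression"))
    for i, j in sorted(ml_pairs):
        out.add(ConstraintRecord(ids[i], ids[j], "ML", "expression"))
    return out
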