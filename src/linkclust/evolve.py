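"""NSGA-II driver with mixed real/integer chromosomes.

A chromosome carries two blocks: a k x d real block of cluster prototypes
in [0, 1], and an integer block of s distinct serial numbers in [1, 2s]
that picks which candidate constraints the individual actually enforces.
Prototype placement and constraint selection are therefore co-optimized:
an individual that selects noisy (label-inconsistent) constraints pays for
it through the penalized objective and is selected against.

Genetic operators follow the real-coded GA toolbox: rank-based roulette
selection, a normal-distribution crossover for the prototype block (one
shared |N(0,1)| draw per coordinate, so the two offspring conserve the
parents' sum before clamping), single-point crossover with duplicate
repair for the selection block, polynomial mutation for prototypes and
single-site random-reset mutation for the selection block. Survivor
selection is the usual elitist (rank, crowding) truncation of the merged
parent + offspring population. The penalty parameter beta doubles at 50%
and 80% of the generation budget, tightening constraint enforcement as
the population converges.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .density import compute_density
from .fuzzy import (
    WeightTriples,
    objective_jp,
    objective_xb,
    update_memberships,
)
from .io import ConstraintRecord, ConstraintSet, ExpressionMatrix
from .ontology import PenaltyWeightMatrix

__all__ = [
    "Chromosome",
    "RankedIndividual",
    "RunConfig",
    "density_peak_centers",
    "initialize_population",
    "roulette_select",
    "crossover_prototypes",
    "crossover_selection",
    "mutate_prototypes",
    "mutate_selection",
    "nondominated_sort_and_crowd",
    "evolve",
]


@dataclass
class Chromosome:
    """Mixed encoding: prototype block (k x d in [0,1]) + selection block.

    ``selection`` holds s distinct 1-based serial numbers into the
    candidate constraint pool of size 2s; s may be 0 (unsupervised run).
    """

    prototypes: np.ndarray
    selection: np.ndarray  # (s,) int

    def validate(self, pool_size: int) -> None:
        if self.prototypes.min() < 0 or self.prototypes.max() > 1:
            raise ValueError("prototype block outside [0, 1]")
        s = len(self.selection)
        if s and (
            len(np.unique(self.selection)) != s
            or self.selection.min() < 1
            or self.selection.max() > pool_size
        ):
            raise ValueError("selection block not distinct in-range serials")


@dataclass
class RankedIndividual:
    chromosome: Chromosome
    fitness: tuple[float, float] = (math.inf, math.inf)  # (XB, J_P)
    f_rank: int = 0
    crowding: float = 0.0
    memberships: np.ndarray | None = None


@dataclass
class RunConfig:
    """All tunables of a clustering run (defaults follow the reference setup)."""

    k: int = 4
    N: int = 100  # population size
    L_max: int = 300  # generations
    eta: float = 0.001  # fuzziness
    beta: float = 0.1  # penalty strength (doubled twice during the run)
    s: int = 15  # constraints selected per individual
    theta: float = 0.5  # ontology action parameter
    alpha: float = 0.3  # rank-selection parameter
    p_c: float = 0.8  # crossover probability
    p_m: float = 0.1  # mutation probability
    eta_m: float = 5.0  # polynomial-mutation distribution index
    epsilon: float = 0.8  # density drop rate
    b: int = 10  # neighbourhood size for density tracking
    passes: int = 10  # membership fixed-point iterations
    tol: float = 1e-6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.s < 0:
            raise ValueError("s must be >= 0")


def density_peak_centers(m: ExpressionMatrix, k: int, b: int = 10) -> np.ndarray:
    """Pick k prototypes by the density-peak rule (largest rho * delta).

    rho is the b-neighbourhood density; delta is the distance to the
    nearest denser gene (for the global density maximum, the largest
    pairwise distance).
    """
    n = m.n
    if k > n:
        raise ValueError(f"k={k} exceeds n={n}")
    rho, _, dist = compute_density(m, min(b, n - 1))
    delta = np.empty(n)
    for i in range(n):
        denser = np.flatnonzero(rho > rho[i])
        delta[i] = dist.max() if len(denser) == 0 else dist[i, denser].min()
    score = rho * delta
    top = np.lexsort((np.arange(n), -score))[:k]
    return m.values[np.sort(top)].copy()


def build_candidate_pool(
    omega: ConstraintSet,
    omega_star: ConstraintSet,
    s: int,
    m: ExpressionMatrix,
    weights: PenaltyWeightMatrix,
    rng: np.random.Generator,
) -> tuple[list[ConstraintRecord], WeightTriples]:
    """Draw the 2s-member candidate pool from the fused constraint union.

    Returns the pool and its weight triples (gene indices, fused w_ij),
    aligned by serial number (pool[g - 1] for serial g).
    """
    union = sorted({rec for rec in omega} | {rec for rec in omega_star})
    if s == 0:
        return [], []
    if len(union) < 2 * s:
        raise ValueError(
            f"need 2s={2 * s} candidate constraints but only {len(union)} available; "
            "reduce s"
        )
    idx = rng.choice(len(union), size=2 * s, replace=False)
    pool = [union[i] for i in idx]
    triples: WeightTriples = []
    for rec in pool:
        i, j = m.index_of(rec.gene_a), m.index_of(rec.gene_b)
        triples.append((min(i, j), max(i, j), weights.get(rec.gene_a, rec.gene_b)))
    return pool, triples


def initialize_population(
    cfg: RunConfig,
    m: ExpressionMatrix,
    pool_size: int,
    rng: np.random.Generator,
) -> list[Chromosome]:
    """Half density-peak, half uniform-random prototype blocks."""
    if cfg.s and pool_size != 2 * cfg.s:
        raise ValueError(f"pool size {pool_size} != 2s = {2 * cfg.s}")
    n_peak = math.ceil(cfg.N / 2)
    peak = density_peak_centers(m, cfg.k, cfg.b)
    population = []
    for r in range(cfg.N):
        if r < n_peak:
            prototypes = peak.copy()
        else:
            prototypes = rng.uniform(0.0, 1.0, size=(cfg.k, m.d))
        if cfg.s:
            selection = 1 + rng.choice(pool_size, size=cfg.s, replace=False)
        else:
            selection = np.empty(0, dtype=int)
        population.append(Chromosome(prototypes=prototypes, selection=selection))
    return population


def roulette_select(
    pop: list[RankedIndividual], alpha: float, rng: np.random.Generator
) -> RankedIndividual:
    """Rank-biased roulette: score alpha * (1 - alpha)^(rank - 1), normalized."""
    scores = np.array([alpha * (1 - alpha) ** (ind.f_rank - 1) for ind in pop])
    probs = scores / scores.sum()
    return pop[rng.choice(len(pop), p=probs)]


def crossover_prototypes(
    a: np.ndarray, b: np.ndarray, rng: np.random.Generator, clamp: bool = True
) -> tuple[np.ndarray, np.ndarray]:
    """Normal-distribution crossover; offspring conserve a + b before clamping.

    One shared |N(0,1)| draw per coordinate places the two offspring
    symmetrically about the parents' midpoint, so off1 + off2 = a + b
    exactly until the [0, 1] clamp is applied.
    """
    z = np.abs(rng.standard_normal(a.shape))
    mid = (a + b) / 2.0
    spread = 1.481 * np.abs(a - b) / 2.0 * z
    off1, off2 = mid + spread, mid - spread
    if clamp:
        off1, off2 = np.clip(off1, 0.0, 1.0), np.clip(off2, 0.0, 1.0)
    return off1, off2


def _repair_duplicates(
    block: np.ndarray, pool_size: int, rng: np.random.Generator
) -> np.ndarray:
    seen: set[int] = set()
    out = block.copy()
    for idx, g in enumerate(out):
        if g in seen:
            unused = np.array(sorted(set(range(1, pool_size + 1)) - seen - set(out[idx + 1 :])))
            out[idx] = rng.choice(unused)
        seen.add(out[idx])
    return out


def crossover_selection(
    a: np.ndarray, b: np.ndarray, pool_size: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Single-point crossover with random repair of duplicate serials."""
    s = len(a)
    if s == 0:
        return a.copy(), b.copy()
    cut = int(rng.integers(1, s + 1))  # cut in [1, s]; cut == s keeps parents
    off1 = np.concatenate([a[:cut], b[cut:]])
    off2 = np.concatenate([b[:cut], a[cut:]])
    return (
        _repair_duplicates(off1, pool_size, rng),
        _repair_duplicates(off2, pool_size, rng),
    )


def _polynomial_delta(rand_m: float, v: float, eta_m: float) -> float:
    # v already normalized to [0, 1]
    p = eta_m + 1.0
    if rand_m < 0.5:
        return (2.0 * rand_m + (1.0 - 2.0 * rand_m) * (1.0 - v) ** p) ** (1.0 / p) - 1.0
    return 1.0 - (2.0 * (1.0 - rand_m) + 2.0 * (rand_m - 0.5) * v**p) ** (1.0 / p)


def mutate_prototypes(
    block: np.ndarray,
    p_m: float,
    eta_m: float,
    rng: np.random.Generator,
    v_l: float = 0.0,
    v_u: float = 1.0,
) -> np.ndarray:
    """Polynomial mutation: each site mutates independently with prob p_m."""
    out = block.copy()
    flat = out.ravel()
    hit = rng.uniform(size=flat.shape) < p_m
    for idx in np.flatnonzero(hit):
        rand_m = float(rng.uniform())
        v_norm = (flat[idx] - v_l) / (v_u - v_l)
        delta = _polynomial_delta(rand_m, v_norm, eta_m)
        flat[idx] = flat[idx] + delta * (v_u - v_l)
    return np.clip(out, v_l, v_u)


def mutate_selection(
    block: np.ndarray, p_m: float, s: int, rng: np.random.Generator
) -> np.ndarray:
    """With prob p_m, reset one random position to an unused serial in [1, 2s]."""
    if len(block) == 0 or rng.uniform() >= p_m:
        return block.copy()
    out = block.copy()
    pos = int(rng.integers(len(out)))
    unused = np.array(sorted(set(range(1, 2 * s + 1)) - set(out.tolist())))
    if len(unused):
        out[pos] = rng.choice(unused)
    return out


def _dominates(f1: tuple[float, float], f2: tuple[float, float]) -> bool:
    return f1[0] <= f2[0] and f1[1] <= f2[1] and (f1[0] < f2[0] or f1[1] < f2[1])


def nondominated_sort_and_crowd(
    fitnesses: list[tuple[float, float]],
) -> tuple[np.ndarray, np.ndarray]:
    """Fast nondominated sort + per-front crowding distance (both minimized)."""
    n = len(fitnesses)
    ranks = np.zeros(n, dtype=int)
    dominated_by: list[list[int]] = [[] for _ in range(n)]
    dominance_count = np.zeros(n, dtype=int)
    for i in range(n):
        for j in range(i + 1, n):
            if _dominates(fitnesses[i], fitnesses[j]):
                dominated_by[i].append(j)
                dominance_count[j] += 1
            elif _dominates(fitnesses[j], fitnesses[i]):
                dominated_by[j].append(i)
                dominance_count[i] += 1
    front = [i for i in range(n) if dominance_count[i] == 0]
    rank = 1
    while front:
        nxt = []
        for i in front:
            ranks[i] = rank
            for j in dominated_by[i]:
                dominance_count[j] -= 1
                if dominance_count[j] == 0:
                    nxt.append(j)
        front = nxt
        rank += 1

    crowding = np.zeros(n)
    fit = np.array(fitnesses, dtype=float)
    for r in range(1, ranks.max() + 1):
        members = np.flatnonzero(ranks == r)
        if len(members) <= 2:
            crowding[members] = np.inf
            continue
        for obj in range(2):
            vals = fit[members, obj]
            order = members[np.argsort(vals, kind="stable")]
            crowding[order[0]] = crowding[order[-1]] = np.inf
            lo, hi = fit[order[0], obj], fit[order[-1], obj]
            if not (np.isfinite(lo) and np.isfinite(hi)) or hi == lo:
                continue
            span = hi - lo
            for a, here, b in zip(order[:-2], order[1:-1], order[2:]):
                if np.isfinite(crowding[here]):
                    crowding[here] += (fit[b, obj] - fit[a, obj]) / span
    return ranks, crowding


def _evaluate(
    chrom: Chromosome,
    m: ExpressionMatrix,
    pool_triples: WeightTriples,
    cfg: RunConfig,
    beta: float,
    force_all: bool,
) -> RankedIndividual:
    """Decode, update memberships against the encoded prototypes, score (XB, J_P)."""
    if force_all:
        triples = pool_triples
    else:
        triples = [pool_triples[g - 1] for g in chrom.selection]
    U = update_memberships(
        m, chrom.prototypes, triples, cfg.eta, beta, cfg.k, cfg.passes, cfg.tol
    )
    # prototypes stay as encoded: with a small fuzziness parameter the
    # memberships are signed and large, so a weighted-mean write-back is
    # numerically destabilizing; refinement is left to the genetic operators
    V = chrom.prototypes
    xb = objective_xb(U, V, m)
    jp = objective_jp(U, V, m, triples, cfg.eta, beta)
    return RankedIndividual(chromosome=chrom, fitness=(xb, jp), memberships=U)


def evolve(
    cfg: RunConfig,
    m: ExpressionMatrix,
    pool_triples: WeightTriples,
    rng: np.random.Generator | None = None,
    force_all_constraints: bool = False,
) -> list[RankedIndividual]:
    """Run the full evolutionary loop; returns the final rank-1 front.

    ``pool_triples`` are the candidate constraints' (i, j, w) entries,
    aligned with the 1-based serial numbers in the selection blocks. With
    s = 0 (empty pool) the penalty term is identically zero and the run
    degenerates to unsupervised two-objective clustering. With
    ``force_all_constraints`` every individual is evaluated against the
    whole pool, disabling constraint selection (ablation baseline).
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    if cfg.s and len(pool_triples) != 2 * cfg.s:
        raise ValueError(f"pool has {len(pool_triples)} triples, expected {2 * cfg.s}")
    pool_size = len(pool_triples)
    beta = cfg.beta
    doublings = {math.ceil(0.5 * cfg.L_max), math.ceil(0.8 * cfg.L_max)}

    chromosomes = initialize_population(cfg, m, pool_size, rng)
    population = [
        _evaluate(c, m, pool_triples, cfg, beta, force_all_constraints)
        for c in chromosomes
    ]
    ranks, crowding = nondominated_sort_and_crowd([p.fitness for p in population])
    for ind, r, cd in zip(population, ranks, crowding):
        ind.f_rank, ind.crowding = int(r), float(cd)

    for gen in range(1, cfg.L_max + 1):
        offspring: list[Chromosome] = []
        while len(offspring) < cfg.N:
            p1 = roulette_select(population, cfg.alpha, rng)
            p2 = roulette_select(population, cfg.alpha, rng)
            v1, v2 = p1.chromosome.prototypes, p2.chromosome.prototypes
            s1, s2 = p1.chromosome.selection, p2.chromosome.selection
            if rng.uniform() < cfg.p_c:
                v1, v2 = crossover_prototypes(v1, v2, rng)
                s1, s2 = crossover_selection(s1, s2, pool_size, rng)
            else:
                v1, v2 = v1.copy(), v2.copy()
                s1, s2 = s1.copy(), s2.copy()
            for v, s in ((v1, s1), (v2, s2)):
                if len(offspring) >= cfg.N:
                    break
                v = mutate_prototypes(v, cfg.p_m, cfg.eta_m, rng)
                s = mutate_selection(s, cfg.p_m, cfg.s, rng)
                offspring.append(Chromosome(prototypes=v, selection=s))
        evaluated = [
            _evaluate(c, m, pool_triples, cfg, beta, force_all_constraints)
            for c in offspring
        ]

        merged = population + evaluated
        ranks, crowding = nondominated_sort_and_crowd([p.fitness for p in merged])
        for ind, r, cd in zip(merged, ranks, crowding):
            ind.f_rank, ind.crowding = int(r), float(cd)
        order = sorted(
            range(len(merged)),
            key=lambda i: (merged[i].f_rank, -merged[i].crowding),
        )
        population = [merged[i] for i in order[: cfg.N]]

        if gen in doublings:
            beta *= 2.0

    ranks, crowding = nondominated_sort_and_crowd([p.fitness for p in population])
    for ind, r, cd in zip(population, ranks, crowding):
        ind.f_rank, ind.crowding = int(r), float(cd)
    return [ind for ind in population if ind.f_rank == 1]
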