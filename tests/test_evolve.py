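import numpy as np
import pytest

from linkclust.evolve import (
    Chromosome,
    RunConfig,
    _polynomial_delta,
    build_candidate_pool,
    crossover_prototypes,
    crossover_selection,
    density_peak_centers,
    evolve,
    initialize_population,
    mutate_prototypes,
    mutate_selection,
    nondominated_sort_and_crowd,
    roulette_select,
)
from linkclust.evolve import RankedIndividual
from linkclust.fuzzy import objective_jp, update_memberships
from linkclust.io import ExpressionMatrix


class FixedRng:
    """Deterministic stand-in for a Generator in operator unit tests."""

    def __init__(self, integers=(), uniforms=(), normals=None):
        self._ints = list(integers)
        self._unis = list(uniforms)
        self._normals = normals

    def integers(self, *args, **kwargs):
        return self._ints.pop(0)

    def uniform(self, *args, **kwargs):
        return self._unis.pop(0)

    def standard_normal(self, shape):
        return np.full(shape, self._normals)

    def choice(self, a, **kwargs):
        arr = np.arange(a) if np.isscalar(a) else np.asarray(a)
        return arr[0]


class TestDensityPeakCenters:
    def test_one_center_per_blob(self, blobs_small):
        m, labels = blobs_small
        centers = density_peak_centers(m, k=2, b=3)
        # each center must lie inside a distinct blob
        owners = set()
        for c in centers:
            dists = np.linalg.norm(m.values - c, axis=1)
            owners.add(labels[int(np.argmin(dists))])
        assert owners == {0, 1}

    def test_k_equals_one_returns_densest(self, blobs_small):
        m, _ = blobs_small
        from linkclust.density import compute_density

        rho, _, _ = compute_density(m, 3)
        center = density_peak_centers(m, k=1, b=3)
        np.testing.assert_array_equal(center[0], m.values[np.argmax(rho)])

    def test_k_equals_n_returns_all(self, collinear3):
        centers = density_peak_centers(collinear3, k=3, b=2)
        np.testing.assert_array_equal(np.sort(centers, axis=0), collinear3.values)

    def test_k_too_large(self, collinear3):
        with pytest.raises(ValueError):
            density_peak_centers(collinear3, k=4)


class TestInitialization:
    def test_half_density_peak_half_random(self, blobs_small):
        m, _ = blobs_small
        cfg = RunConfig(k=2, N=4, s=2, b=3, seed=0)
        rng = np.random.default_rng(0)
        pop = initialize_population(cfg, m, pool_size=4, rng=rng)
        assert len(pop) == 4
        peak = density_peak_centers(m, 2, 3)
        np.testing.assert_array_equal(pop[0].prototypes, peak)
        np.testing.assert_array_equal(pop[1].prototypes, peak)
        assert not np.array_equal(pop[2].prototypes, peak)
        for chrom in pop:
            chrom.validate(pool_size=4)

    def test_seed_reproducibility(self, blobs_small):
        m, _ = blobs_small
        cfg = RunConfig(k=2, N=6, s=3, b=3, seed=5)
        pop1 = initialize_population(cfg, m, 6, np.random.default_rng(5))
        pop2 = initialize_population(cfg, m, 6, np.random.default_rng(5))
        for a, b in zip(pop1, pop2):
            np.testing.assert_array_equal(a.prototypes, b.prototypes)
            np.testing.assert_array_equal(a.selection, b.selection)


class TestRoulette:
    def test_scores_follow_rank_geometric_decay(self):
        pop = [
            RankedIndividual(Chromosome(np.zeros((1, 1)), np.empty(0, int)), f_rank=r)
            for r in (1, 2, 3)
        ]
        alpha = 0.3
        counts = np.zeros(3)
        rng = np.random.default_rng(0)
        draws = 100_000
        for _ in range(draws):
            picked = roulette_select(pop, alpha, rng)
            counts[picked.f_rank - 1] += 1
        scores = np.array([alpha * (1 - alpha) ** (r - 1) for r in (1, 2, 3)])
        probs = scores / scores.sum()
        sigma = np.sqrt(probs * (1 - probs) * draws)
        assert (np.abs(counts - probs * draws) < 3 * sigma).all()

    def test_equal_ranks_uniform(self):
        pop = [
            RankedIndividual(Chromosome(np.zeros((1, 1)), np.empty(0, int)), f_rank=1)
            for _ in range(4)
        ]
        rng = np.random.default_rng(1)
        picks = {id(roulette_select(pop, 0.3, rng)) for _ in range(200)}
        assert len(picks) == 4


class TestCrossover:
    def test_identical_parents_unchanged(self):
        a = np.full((2, 2), 0.4)
        off1, off2 = crossover_prototypes(a, a.copy(), np.random.default_rng(0))
        np.testing.assert_array_equal(off1, a)
        np.testing.assert_array_equal(off2, a)

    def test_sum_conservation_preclamp(self):
        rng = np.random.default_rng(3)
        a, b = rng.uniform(0, 1, (2, 3, 4))
        off1, off2 = crossover_prototypes(a, b, rng, clamp=False)
        np.testing.assert_allclose(off1 + off2, a + b, atol=1e-15)

    def test_zero_draw_gives_midpoint(self):
        a = np.array([[0.2]])
        b = np.array([[0.8]])
        off1, off2 = crossover_prototypes(a, b, FixedRng(normals=0.0))
        np.testing.assert_allclose(off1, 0.5)
        np.testing.assert_allclose(off2, 0.5)

    def test_selection_cut_at_s_keeps_parents(self):
        a = np.array([1, 2, 3])
        b = np.array([4, 5, 6])
        off1, off2 = crossover_selection(a, b, 6, FixedRng(integers=[3]))
        np.testing.assert_array_equal(off1, a)
        np.testing.assert_array_equal(off2, b)

    def test_duplicate_repair(self):
        a = np.array([1, 2, 3])
        b = np.array([3, 4, 5])
        rng = np.random.default_rng(0)

        class CutThenReal:
            def integers(self, *args, **kwargs):
                return 1

            def choice(self, arr, **kw):
                return rng.choice(arr, **kw)

        off1, off2 = crossover_selection(a, b, 6, CutThenReal())
        np.testing.assert_array_equal(off1, [1, 4, 5])
        assert off2[0] == 3 and off2[1] == 2
        assert len(np.unique(off2)) == 3 and off2.min() >= 1 and off2.max() <= 6

    def test_offspring_always_distinct(self):
        rng = np.random.default_rng(9)
        for _ in range(100):
            s = int(rng.integers(2, 6))
            pool = 2 * s
            a = 1 + rng.choice(pool, s, replace=False)
            b = 1 + rng.choice(pool, s, replace=False)
            for off in crossover_selection(a, b, pool, rng):
                assert len(np.unique(off)) == s
                assert off.min() >= 1 and off.max() <= pool


class TestMutation:
    def test_delta_zero_at_half(self):
        assert _polynomial_delta(0.5, 0.3, 5.0) == pytest.approx(0.0)

    def test_delta_lower_extreme(self):
        # rand_m = 0 pulls the site to the lower bound: delta = -v
        for v in (0.0, 0.25, 0.9):
            assert _polynomial_delta(0.0, v, 5.0) == pytest.approx(-v)

    def test_delta_bounded_on_grid(self):
        for rand_m in np.linspace(0, 1, 101):
            for v in np.linspace(0, 1, 101):
                assert -1.0 - 1e-12 <= _polynomial_delta(rand_m, v, 5.0) <= 1.0 + 1e-12

    def test_prototype_mutation_stays_in_bounds(self):
        rng = np.random.default_rng(2)
        block = rng.uniform(0, 1, (3, 4))
        out = mutate_prototypes(block, p_m=1.0, eta_m=5.0, rng=rng)
        assert out.min() >= 0 and out.max() <= 1
        assert not np.array_equal(out, block)

    def test_selection_mutation_identity_when_pm_zero(self):
        block = np.array([1, 3, 5])
        out = mutate_selection(block, 0.0, 3, np.random.default_rng(0))
        np.testing.assert_array_equal(out, block)

    def test_selection_mutation_flips_only_unused(self):
        out = mutate_selection(np.array([1]), 1.0, 1, np.random.default_rng(0))
        np.testing.assert_array_equal(out, [2])

    def test_selection_mutation_valid(self):
        rng = np.random.default_rng(4)
        block = np.array([2, 4, 6])
        for _ in range(50):
            out = mutate_selection(block, 1.0, 3, rng)
            assert len(np.unique(out)) == 3
            assert out.min() >= 1 and out.max() <= 6


class TestNondominatedSort:
    def test_single_individual(self):
        ranks, crowd = nondominated_sort_and_crowd([(1.0, 2.0)])
        assert ranks[0] == 1 and crowd[0] == np.inf

    def test_dominated_chain(self):
        ranks, _ = nondominated_sort_and_crowd([(3.0, 3.0), (1.0, 1.0), (2.0, 2.0)])
        np.testing.assert_array_equal(ranks, [3, 1, 2])

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(0)
        fits = [tuple(x) for x in rng.uniform(0, 1, (200, 2))]
        ranks, _ = nondominated_sort_and_crowd(fits)

        def brute_ranks(points):
            points = list(enumerate(points))
            out = np.zeros(len(points), dtype=int)
            rank = 1
            remaining = points
            while remaining:
                front = [
                    (i, p)
                    for i, p in remaining
                    if not any(
                        (q[0] <= p[0] and q[1] <= p[1] and q != p)
                        for _, q in remaining
                    )
                ]
                for i, _ in front:
                    out[i] = rank
                remaining = [x for x in remaining if x not in front]
                rank += 1
            return out

        np.testing.assert_array_equal(ranks, brute_ranks(fits))


@pytest.fixture(scope="module")
def small_setup(blobs_small):
    m, labels = blobs_small
    from linkclust.density import fit_density_model, generate_expression_constraints
    from linkclust.ontology import fuse_weights
    from linkclust.io import ConstraintSet

    model = fit_density_model(m, 3)
    omega = generate_expression_constraints(model, m, n_cl=6, n_ml=6)
    W, pruned, _ = fuse_weights(omega, ConstraintSet(), 0.5)
    cfg = RunConfig(k=2, N=8, L_max=5, s=4, b=3, seed=0)
    pool, triples = build_candidate_pool(
        pruned, ConstraintSet(), cfg.s, m, W, np.random.default_rng(0)
    )
    return m, cfg, triples


class TestEvolve:
    def test_deterministic_under_seed(self, small_setup):
        m, cfg, triples = small_setup
        f1 = evolve(cfg, m, triples, rng=np.random.default_rng(3))
        f2 = evolve(cfg, m, triples, rng=np.random.default_rng(3))
        assert [i.fitness for i in f1] == [i.fitness for i in f2]
        for a, b in zip(f1, f2):
            np.testing.assert_array_equal(a.chromosome.prototypes, b.chromosome.prototypes)

    def test_front_is_rank_one_and_valid(self, small_setup):
        m, cfg, triples = small_setup
        front = evolve(cfg, m, triples, rng=np.random.default_rng(1))
        assert front
        fits = [i.fitness for i in front]
        for a in fits:
            for b in fits:
                assert not (a[0] < b[0] and a[1] < b[1]) or a == b
        for ind in front:
            assert ind.f_rank == 1
            ind.chromosome.validate(pool_size=2 * cfg.s)

    def test_unsupervised_run_has_zero_penalty(self, blobs_small):
        """With s = 0 the fitness equals the penalty-free objective exactly."""
        m, _ = blobs_small
        cfg = RunConfig(k=2, N=6, L_max=4, s=0, b=3, seed=2)
        front = evolve(cfg, m, [], rng=np.random.default_rng(2))
        for ind in front:
            U = ind.memberships
            V = ind.chromosome.prototypes
            jp_nopen = objective_jp(U, V, m, [], cfg.eta, 0.0)
            assert ind.fitness[1] == pytest.approx(jp_nopen, abs=1e-12)

    def test_pool_size_mismatch_rejected(self, small_setup):
        m, cfg, triples = small_setup
        with pytest.raises(ValueError):
            evolve(cfg, m, triples[:3], rng=np.random.default_rng(0))


def test_build_candidate_pool_too_small(blobs_small):
    from linkclust.io import ConstraintSet
    from linkclust.ontology import PenaltyWeightMatrix

    m, _ = blobs_small
    with pytest.raises(ValueError, match="reduce s"):
        build_candidate_pool(
            ConstraintSet(),
            ConstraintSet(),
            5,
            m,
            PenaltyWeightMatrix(theta=0.5),
            np.random.default_rng(0),
        )
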