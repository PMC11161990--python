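"""Algorithm-specific mechanisms and shared run contracts."""

import numpy as np
import pytest

from molmoo.fixtures import toy_problem
from molmoo.metrics import exact_hypervolume
from molmoo.optimizers import (ALGORITHMS, AlgorithmParams,
                               initialize_population, nondominated_sort)
from molmoo.optimizers.ansga3 import (_AdaptiveRefs, associate,
                                      normalize_objectives)
from molmoo.optimizers.grea import grid_coordinates, grid_crowding_degrees
from molmoo.optimizers.hype import hype_fitness
from molmoo.optimizers.knea import hyperplane_distances, identify_knees
from molmoo.optimizers.moeadd import pbi
from molmoo.optimizers.refpoints import das_dennis, default_reference_points

DESK = AlgorithmParams(population_size=20, max_evaluations=120)


def _problem_and_init(library, seed=42, size=20):
    problem = toy_problem(4, library=library, seed=0)
    initial = initialize_population(library, problem, size, seed)
    return problem, initial


class TestSharedContracts:
    @pytest.mark.parametrize("name", sorted(ALGORITHMS))
    def test_budget_population_and_front_consistency(self, name,
                                                     small_library):
        problem, initial = _problem_and_init(small_library)
        history = ALGORITHMS[name](problem, DESK, initial, 42)
        assert history.evaluations_used <= DESK.max_evaluations
        assert len(history.final.smiles) == DESK.population_size
        F = history.final.objectives
        front = history.final.nondominated()
        from molmoo.optimizers.core import dominates
        for f in front:
            assert not any(dominates(g, f) for g in F)

    @pytest.mark.parametrize("name", ["grea", "moeadd", "nmpso"])
    def test_seeded_runs_bit_reproducible(self, name, small_library):
        finals = []
        for _ in range(2):
            problem, initial = _problem_and_init(small_library, seed=7)
            history = ALGORITHMS[name](problem, DESK, initial, 7)
            finals.append(history.final.objectives)
        assert np.array_equal(finals[0], finals[1])

    def test_initialization_contract(self, small_library):
        problem, initial = _problem_and_init(small_library, seed=3, size=40)
        smiles = [ind.smiles for ind in initial]
        assert len(set(smiles)) == 40
        _, replay = _problem_and_init(small_library, seed=3, size=40)
        assert [i.smiles for i in replay] == smiles
        from molmoo.metrics import novelty
        assert novelty(smiles, small_library) == 0.0

    def test_initialization_requires_enough_molecules(self, small_library):
        problem = toy_problem(4, library=small_library)
        with pytest.raises(Exception):
            initialize_population(small_library[:5], problem, 40, 0)


class TestGrEA:
    def test_same_cell_pair_has_higher_crowding(self):
        # hand grid: two coincident points share a cell; the far point does not
        F = np.array([[0.05, 0.05], [0.06, 0.06], [0.9, 0.9]])
        gcd = grid_crowding_degrees(F, div=8)
        assert gcd[0] == gcd[1] > gcd[2]

    def test_grid_adapts_to_population_extent(self):
        F = np.array([[0.0, 0.0], [8.0, 4.0]])
        G = grid_coordinates(F, div=8)
        assert G[0].min() >= 0
        assert np.all(G <= 8)
        # widening the population must change cell assignment scale
        G2 = grid_coordinates(F * 10, div=8)
        assert np.array_equal(G, G2)        # relative layout is scale-free


class TestHypE:
    def test_dominated_point_has_smallest_contribution(self, rng):
        F = np.array([[0.1, 0.2], [0.3, 0.1], [0.8, 0.9]])  # last dominated
        fit = hype_fitness(F, k=1, n_sample=20_000, rng=rng)
        assert fit.argmin() == 2

    def test_sampled_ranking_matches_exact_contributions(self):
        agree = 0
        for rep in range(100):
            rng = np.random.default_rng(1000 + rep)
            F = rng.uniform(0.0, 1.0, size=(3, 2))
            ref = np.full(2, 1.2)
            exact = np.array([
                exact_hypervolume(F, ref)
                - exact_hypervolume(np.delete(F, i, axis=0), ref)
                for i in range(3)])
            sampled = hype_fitness(F, k=1, n_sample=100_000, rng=rng,
                                   reference=ref)
            if np.array_equal(np.argsort(exact), np.argsort(sampled)):
                agree += 1
        assert agree >= 95


class TestKnEA:
    def test_middle_of_bulged_front_is_knee(self):
        # symmetric front bulging toward the origin; middle point deepest
        F = np.array([[0.0, 1.0], [0.05, 0.55], [0.3, 0.3],
                      [0.55, 0.05], [1.0, 0.0]])
        knees, dist = identify_knees(F, radius_fraction=0.01)
        assert dist.argmax() == 2
        assert knees[2]

    def test_collinear_front_degenerates_gracefully(self):
        F = np.array([[0.0, 1.0], [0.25, 0.75], [0.5, 0.5], [1.0, 0.0]])
        knees, dist = identify_knees(F, radius_fraction=0.1)
        assert np.allclose(dist[1:3], 0.0, atol=1e-9)
        assert knees.any()                  # fallback ordering still selects

    def test_distances_zero_on_singular_extremes(self):
        F = np.array([[1.0, 1.0], [1.0, 1.0]])
        assert np.allclose(hyperplane_distances(F), 0.0)


class TestMOEADD:
    def test_pbi_on_own_ray_has_no_penalty(self):
        w = np.array([0.6, 0.8])
        point = 2.5 * w / np.linalg.norm(w)
        value = pbi(point, w, np.zeros(2), theta=5.0)
        assert np.isclose(value, 2.5)

    def test_pbi_matches_manual_decomposition(self, rng):
        for _ in range(25):
            f = rng.uniform(0, 5, size=3)
            w = rng.uniform(0.1, 1, size=3)
            ideal = rng.uniform(-1, 0, size=3)
            wn = w / np.linalg.norm(w)
            d1 = (f - ideal) @ wn
            d2 = np.linalg.norm(f - ideal - d1 * wn)
            assert np.isclose(pbi(f, w, ideal, 5.0), d1 + 5.0 * d2)


class TestANSGA3:
    def test_weight_vectors_lie_on_simplex(self):
        for m, h in ((2, 10), (3, 6), (4, 4)):
            W = das_dennis(m, h)
            assert np.allclose(W.sum(axis=1), 1.0)
            assert np.all(W >= 0)
        W6 = default_reference_points(6, 40)
        assert np.allclose(W6.sum(axis=1), 1.0)

    def test_association_matches_brute_force(self, rng):
        FN = rng.uniform(0, 1, size=(20, 3))
        refs = das_dennis(3, 4)
        niche, dist = associate(FN, refs)
        R = refs / np.linalg.norm(refs, axis=1, keepdims=True)
        for i in range(20):
            perp = [np.linalg.norm(FN[i] - (FN[i] @ R[j]) * R[j])
                    for j in range(len(refs))]
            assert niche[i] == int(np.argmin(perp))
            assert np.isclose(dist[i], min(perp))

    def test_normalization_uses_monotone_ideal(self, rng):
        F = rng.uniform(1, 2, size=(12, 3))
        ideal = F.min(axis=0) - 0.1
        FN = normalize_objectives(F, ideal)
        assert np.all(FN >= 0)

    def test_adaptive_points_added_then_removed(self):
        base = das_dennis(2, 4)
        refs = _AdaptiveRefs(base)
        crowded = np.zeros(len(base), dtype=int)
        crowded[2] = 3                      # crowded niche -> insert simplex
        refs.adapt(crowded)
        assert len(refs.extra) > 0
        emptied = np.zeros(len(base) + len(refs.extra), dtype=int)
        refs.adapt(emptied)                 # inserted niches now empty
        assert len(refs.extra) == 0


class TestNMPSO:
    def test_stationary_particle_with_coincident_guides(self, small_library):
        # a swarm of one molecule: pbest = gbest = abest = x and v = 0,
        # mutation disabled -> the particle must not move
        problem = toy_problem(4, library=small_library)
        one = small_library[0]
        initial = initialize_population([one] * 1 + small_library[:0],
                                        problem, 1, 0)
        params = AlgorithmParams(population_size=2, max_evaluations=4,
                                 p_m=0.0)
        history = ALGORITHMS["nmpso"](problem, params, initial * 2, 0)
        for snap in history.generations:
            assert set(snap.smiles) == {one}

    def test_archive_mutually_nondominated(self, small_library):
        from molmoo.optimizers.core import dominates
        problem, initial = _problem_and_init(small_library)
        history = ALGORITHMS["nmpso"](problem, DESK, initial, 11)
        front = history.final.nondominated()
        for i, f in enumerate(front):
            assert not any(dominates(g, f) for g in front)

    def test_positions_stay_in_bounds(self, small_library):
        problem, initial = _problem_and_init(small_library)
        history = ALGORITHMS["nmpso"](problem, DESK, initial, 5)
        assert problem.bounds is not None   # bounds derived at initialization
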