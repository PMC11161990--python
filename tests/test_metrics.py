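"""GD/IGD, uniqueness/novelty, Wasserstein, exact hypervolume, reports."""

import numpy as np
import pytest

from molmoo import metrics as mx
from molmoo.optimizers.core import GenerationSnapshot, RunHistory


def brute_force_gd(A, R):
    return np.mean([min(np.linalg.norm(a - r) for r in R) for a in A])


class TestGDIGD:
    def test_identical_fronts_are_zero(self, rng):
        F = rng.normal(size=(7, 3))
        assert mx.gd(F, F) == 0.0
        assert mx.igd(F, F) == 0.0

    def test_hand_geometry(self):
        assert np.isclose(mx.gd([[1.0, 1.0]], [[0.0, 0.0]]), np.sqrt(2))

    def test_matches_nested_loop_oracle(self, rng):
        for _ in range(20):
            A = rng.normal(size=(rng.integers(1, 12), 4))
            R = rng.normal(size=(rng.integers(1, 12), 4))
            assert np.isclose(mx.gd(A, R), brute_force_gd(A, R))
            assert np.isclose(mx.igd(A, R), brute_force_gd(R, A))

    def test_gd_igd_symmetry(self, rng):
        A = rng.normal(size=(6, 3))
        R = rng.normal(size=(9, 3))
        assert np.isclose(mx.gd(A, R), mx.igd(R, A))

    def test_permutation_invariance(self, rng):
        A = rng.normal(size=(8, 2))
        R = rng.normal(size=(5, 2))
        perm = rng.permutation(8)
        assert np.isclose(mx.gd(A, R), mx.gd(A[perm], R))

    def test_covering_a_reference_point_decreases_igd(self, rng):
        A = rng.normal(size=(4, 2))
        R = rng.normal(size=(6, 2)) + 10.0
        improved = np.vstack([A, R[2]])
        assert mx.igd(improved, R) < mx.igd(A, R)

    def test_empty_front_rejected(self):
        with pytest.raises(ValueError):
            mx.gd(np.empty((0, 2)), [[0.0, 0.0]])


def _history(objectives_per_gen, smiles_per_gen, algorithm="x", seed=0):
    hist = RunHistory(algorithm=algorithm, seed=seed)
    for F, smi in zip(objectives_per_gen, smiles_per_gen):
        hist.generations.append(GenerationSnapshot(
            objectives=np.asarray(F, float), smiles=list(smi)))
    return hist


class TestReferenceFront:
    def test_single_run_gives_own_nondominated_set(self):
        F = [[0.0, 1.0], [1.0, 0.0], [2.0, 2.0]]
        hist = _history([F], [["a", "b", "c"]])
        ref = mx.build_reference_front([hist])
        assert sorted(ref.tolist()) == [[0.0, 1.0], [1.0, 0.0]]

    def test_dominated_run_does_not_change_union(self):
        good = _history([[[0.0, 1.0], [1.0, 0.0]]], [["a", "b"]])
        bad = _history([[[5.0, 5.0], [6.0, 7.0]]], [["c", "d"]])
        assert np.array_equal(mx.build_reference_front([good, bad]),
                              mx.build_reference_front([good]))

    def test_matches_pairwise_oracle(self, rng):
        from molmoo.optimizers.core import dominates
        F = rng.normal(size=(30, 3))
        hist = _history([F[:15], F[15:]], [["m"] * 15, ["m"] * 15])
        ref = mx.build_reference_front([hist], final_only=False)
        expected = [f for f in F
                    if not any(dominates(g, f) for g in F)]
        assert sorted(ref.tolist()) == sorted(np.unique(
            np.asarray(expected), axis=0).tolist())


class TestPopulationMetrics:
    def test_uniqueness_counts(self):
        assert mx.uniqueness(["CCO", "CCO", "CCN", "CCC"]) == 0.75
        assert mx.uniqueness(["CCO"] * 4) == 0.25
        assert mx.uniqueness(["CCO", "CCN"]) == 1.0

    def test_uniqueness_canonicalizes_spellings(self):
        assert mx.uniqueness(["CCO", "OCC"]) == 0.5

    def test_novelty_extremes_and_half_overlap(self):
        train = ["CCO", "CCN"]
        assert mx.novelty(["CCO", "CCN"], train) == 0.0
        assert mx.novelty(["CCC", "CCCC"], train) == 1.0
        assert mx.novelty(["CCO", "CCC"], train) == 0.5


class TestWasserstein:
    def test_identical_samples_zero(self, rng):
        x = rng.normal(size=50)
        assert mx.wasserstein_1d(x, x) == 0.0

    def test_point_masses(self):
        assert np.isclose(mx.wasserstein_1d([3.0], [-1.5]), 4.5)

    def test_matches_ecdf_integral_oracle(self, rng):
        for _ in range(5):
            p = rng.normal(size=40)
            q = rng.normal(1.0, 2.0, size=25)
            grid = np.linspace(min(p.min(), q.min()) - 1,
                               max(p.max(), q.max()) + 1, 200_001)
            ecdf_p = np.searchsorted(np.sort(p), grid, side="right") / p.size
            ecdf_q = np.searchsorted(np.sort(q), grid, side="right") / q.size
            oracle = np.trapezoid(np.abs(ecdf_p - ecdf_q), grid)
            assert abs(mx.wasserstein_1d(p, q) - oracle) < 1e-4


class TestExactHypervolume:
    def test_unit_square(self):
        assert mx.exact_hypervolume([[1.0, 1.0]], [2.0, 2.0]) == 1.0

    def test_dominated_point_adds_nothing(self):
        base = mx.exact_hypervolume([[1.0, 1.0]], [3.0, 3.0])
        both = mx.exact_hypervolume([[1.0, 1.0], [2.0, 2.0]], [3.0, 3.0])
        assert base == both

    def test_point_beyond_reference_contributes_zero(self):
        assert mx.exact_hypervolume([[4.0, 1.0]], [3.0, 3.0]) == 0.0

    @pytest.mark.parametrize("m", [2, 3])
    def test_matches_grid_monte_carlo(self, m, rng):
        for _ in range(10):
            pts = rng.uniform(0, 1, size=(rng.integers(2, 9), m))
            ref = np.full(m, 1.2)
            exact = mx.exact_hypervolume(pts, ref)
            samples = rng.uniform(0, 1.2, size=(200_000, m))
            dominated = np.any(np.all(samples[:, None, :] >= pts[None, :, :],
                                      axis=2), axis=1)
            mc = dominated.mean() * 1.2 ** m
            assert abs(exact - mc) <= 0.01 * max(mc, 1e-6) + 0.002

    def test_four_objectives_rejected(self):
        with pytest.raises(ValueError):
            mx.exact_hypervolume(np.zeros((2, 4)), np.ones(4))


def test_make_report_numbers_match_recomputation(tmp_path, rng):
    histories = []
    train = ["CCO", "CCN", "CCC"]
    for seed in (0, 1):
        gens = [rng.normal(size=(6, 2)) + g for g in range(3)]
        smiles = [["CCO", "CCN", "CCC", "CCCC", "CCCC", "c1ccccc1"]] * 3
        histories.append(_history(gens, smiles, algorithm="alg", seed=seed))
    report = mx.make_report(histories, train, str(tmp_path))
    curves = report["curves"]
    assert len(curves) == 2 * 3            # one row per generation per seed
    ref = mx.build_reference_front(histories)
    row = curves[(curves.seed == 1) & (curves.generation == 2)].iloc[0]
    snap = histories[1].generations[2]
    assert np.isclose(row["gd"], mx.gd(snap.nondominated(), ref))
    assert np.isclose(row["uniqueness"], mx.uniqueness(snap.smiles))
    init = np.vstack([h.generations[0].objectives for h in histories])
    fin = np.vstack([h.final.objectives for h in histories])
    assert np.isclose(report["wasserstein"]["f0"],
                      mx.wasserstein_1d(init[:, 0], fin[:, 0]))
    assert (tmp_path / "curve_gd.png").exists()
    assert (tmp_path / "summary.csv").exists()
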