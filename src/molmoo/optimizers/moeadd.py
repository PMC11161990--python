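"""MOEA/DD: dominance- and decomposition-based evolutionary algorithm.

The objective space is decomposed by Das–Dennis weight vectors; each
solution is associated with the weight region whose ray it is closest to
(perpendicular distance).  Offspring mate within a weight neighbourhood of
size ``T`` with probability ``delta`` (otherwise population-wide) and are
inserted steady-state: the update removes, from the worst Pareto front,
a member of the most crowded region — the one with the largest
penalty-based boundary intersection (PBI) value, d1 + theta*d2 along its
region's ray — blending convergence (dominance), diversity (region
density) and decomposition (PBI).
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .core import (AlgorithmParams, Individual, LatentProblem, RunHistory,
                   nondominated_sort, polynomial_mutation, sbx_crossover)
from .refpoints import default_reference_points

__all__ = ["run_moeadd", "pbi"]


def pbi(f: np.ndarray, weight: np.ndarray, ideal: np.ndarray,
        theta: float) -> float:
    """Penalty-based boundary intersection of point ``f`` on ``weight``'s ray."""
    w = weight / np.linalg.norm(weight)
    shifted = f - ideal
    d1 = float(shifted @ w)
    d2 = float(np.linalg.norm(shifted - d1 * w))
    return d1 + theta * d2


def _associate(F: np.ndarray, W: np.ndarray, ideal: np.ndarray) -> np.ndarray:
    """Region index per solution: nearest weight ray by perpendicular distance."""
    shifted = F - ideal
    Wn = W / np.linalg.norm(W, axis=1, keepdims=True)
    d1 = shifted @ Wn.T                                    # (n, R)
    perp = np.linalg.norm(shifted[:, None, :] - d1[..., None] * Wn[None, :, :],
                          axis=2)
    return perp.argmin(axis=1)


def run_moeadd(problem: LatentProblem, params: AlgorithmParams,
               initial: Sequence[Individual], seed: int) -> RunHistory:
    rng = np.random.default_rng(seed)
    history = RunHistory(algorithm="moeadd", seed=seed)
    population = list(initial)
    N = len(population)
    W = default_reference_points(problem.n_objectives, N)
    T = min(params.moeadd_neighbors, len(W) - 1, N - 1)
    wdist = np.linalg.norm(W[:, None, :] - W[None, :, :], axis=2)
    neighbours = np.argsort(wdist, axis=1)[:, :max(T, 1)]
    history.record(population)

    def ideal_of(pop):
        return np.stack([ind.f for ind in pop]).min(axis=0)

    while True:
        budget = min(params.population_size, problem.remaining(params))
        if budget < 2:
            break
        new_batch = 0
        for _ in range(budget):
            F = np.stack([ind.f for ind in population])
            ideal = F.min(axis=0)
            regions = _associate(F, W, ideal)
            region = int(rng.integers(len(W)))
            if rng.random() < params.moeadd_delta:
                pool = np.flatnonzero(np.isin(regions, neighbours[region]))
                if pool.size < 2:
                    pool = np.arange(len(population))
            else:
                pool = np.arange(len(population))
            a, b = rng.choice(pool, size=2, replace=pool.size < 2)
            c1, _ = sbx_crossover(population[int(a)].z, population[int(b)].z,
                                  problem.bounds, params.eta_c, params.p_c, rng)
            c1 = polynomial_mutation(c1, problem.bounds, params.eta_m,
                                     params.p_m, rng)
            child = problem.repair_and_evaluate(c1[None, :])[0]
            population.append(child)
            new_batch += 1
            # steady-state removal: worst front -> most crowded region ->
            # largest PBI
            F = np.stack([ind.f for ind in population])
            ideal = F.min(axis=0)
            regions = _associate(F, W, ideal)
            worst_front = nondominated_sort(F)[-1]
            counts = np.bincount(regions[worst_front], minlength=len(W))
            crowded = int(counts.argmax())
            candidates = [i for i in worst_front if regions[i] == crowded]
            doomed = max(candidates,
                         key=lambda i: pbi(F[i], W[regions[i]], ideal,
                                           params.moeadd_theta))
            population.pop(doomed)
        history.record(population)
        if new_batch == 0:
            break
    history.evaluations_used = problem.evaluations
    return history
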