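"""KnEA: knee-point-driven evolutionary algorithm.

Within each front, a hyperplane is fitted through the extreme solutions
(the maximizers of each objective); a solution's distance *below* that
hyperplane measures how strong a trade-off it offers, and the solution with
the maximal distance inside its neighbourhood is a knee.  Neighbourhood
size adapts each generation at a rate controlled by ``T`` (the target knee
ratio).  Knees are preferred both in binary tournaments and when the
critical front is truncated.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .common import make_offspring
from .core import (AlgorithmParams, Individual, LatentProblem, RunHistory,
                   front_ranks, nondominated_sort)

__all__ = ["run_knea", "hyperplane_distances", "identify_knees"]


def hyperplane_distances(F: np.ndarray) -> np.ndarray:
    """Signed distance of each point below the extreme-point hyperplane.

    The hyperplane passes through the per-objective maximizers of the
    front; larger values mean further below (stronger knees).  Degenerate
    (collinear/singular) extreme sets fall back to zero distances.
    """
    F = np.atleast_2d(np.asarray(F, dtype=float))
    n, m = F.shape
    extremes = F[np.argmax(F, axis=0)]
    try:
        coeffs = np.linalg.solve(extremes, np.ones(m))
    except np.linalg.LinAlgError:
        return np.zeros(n)
    norm = np.linalg.norm(coeffs)
    if norm < 1e-12 or not np.all(np.isfinite(coeffs)):
        return np.zeros(n)
    return (1.0 - F @ coeffs) / norm


def identify_knees(F: np.ndarray, radius_fraction: float
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Knee flags and hyperplane distances for one front.

    A solution is a knee if no neighbour (within an axis-aligned box of
    half-width ``radius_fraction`` of each objective's span) has a larger
    hyperplane distance.
    """
    F = np.atleast_2d(np.asarray(F, dtype=float))
    n, m = F.shape
    dist = hyperplane_distances(F)
    span = F.max(axis=0) - F.min(axis=0)
    radius = np.where(span > 0, span * radius_fraction, 1.0)
    knee = np.zeros(n, dtype=bool)
    order = np.argsort(-dist)
    blocked = np.zeros(n, dtype=bool)
    for i in order:
        if blocked[i]:
            continue
        knee[i] = True
        neighbours = np.all(np.abs(F - F[i]) <= radius, axis=1)
        blocked |= neighbours
    return knee, dist


class _KneaState:
    def __init__(self, t: float):
        self.t = t
        self.radius = 0.5
        self.knee_ratio = 0.0

    def update_radius(self, m: int) -> None:
        self.radius = self.radius * np.exp(-(1.0 - self.knee_ratio / self.t) / m)


def run_knea(problem: LatentProblem, params: AlgorithmParams,
             initial: Sequence[Individual], seed: int) -> RunHistory:
    rng = np.random.default_rng(seed)
    history = RunHistory(algorithm="knea", seed=seed)
    population = list(initial)
    history.record(population)
    state = _KneaState(params.knea_t)
    while True:
        n = min(params.population_size, problem.remaining(params))
        if n < 2:
            break
        F = np.stack([ind.f for ind in population])
        ranks = front_ranks(F)
        knees = np.zeros(len(population), dtype=bool)
        dists = np.zeros(len(population))
        n_knees = 0
        for front in nondominated_sort(F):
            flags, dist = identify_knees(F[front], state.radius)
            knees[front] = flags
            dists[front] = dist
            n_knees += int(flags.sum())
        state.knee_ratio = n_knees / len(population)
        state.update_radius(F.shape[1])
        # Tournament: lower rank, then knee preferred, then larger distance.
        keys = list(zip(ranks.tolist(), (~knees).tolist(), (-dists).tolist()))
        offspring = make_offspring(population, keys, n, problem, params, rng)

        union = population + offspring
        FU = np.stack([ind.f for ind in union])
        fronts = nondominated_sort(FU)
        chosen: list[int] = []
        for front in fronts:
            if len(chosen) + len(front) <= len(population):
                chosen.extend(front.tolist())
                continue
            need = len(population) - len(chosen)
            flags, dist = identify_knees(FU[front], state.radius)
            # knees first, then by hyperplane distance; seeded jitter breaks
            # exact ties reproducibly
            order = sorted(range(len(front)),
                           key=lambda i: (not flags[i], -dist[i],
                                          rng.random()))
            chosen.extend(front[order[:need]].tolist())
            break
        population = [union[i] for i in chosen]
        history.record(population)
    history.evaluations_used = problem.evaluations
    return history
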