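"""HypE: hypervolume estimation evolutionary algorithm.

Fitness is each solution's share of the dominated hypervolume, estimated by
Monte Carlo: sample points uniformly in the box between the ideal and a
reference point; a sample dominated by exactly ``i`` solutions credits each
of them with a weight ``alpha_i / i`` (the HypE weighting for removing ``k``
solutions), so fitness concentrates on regions a solution dominates nearly
exclusively.  Environmental selection keeps whole fronts and prunes the
critical front by iteratively removing the solution with the smallest
estimated contribution.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .common import generational_run
from .core import (AlgorithmParams, Individual, LatentProblem, RunHistory,
                   front_ranks, nondominated_sort)

__all__ = ["run_hype", "hype_fitness"]


def _alpha(k: int, n: int) -> np.ndarray:
    """HypE weights alpha_i for i = 1..n when k solutions are to be removed."""
    alpha = np.zeros(n + 1)
    for i in range(1, n + 1):
        prod = 1.0
        for j in range(1, i):
            prod *= (k - j) / (n - j)
        alpha[i] = prod / i
    return alpha


def hype_fitness(F: np.ndarray, k: int, n_sample: int,
                 rng: np.random.Generator,
                 reference: np.ndarray | None = None) -> np.ndarray:
    """Monte Carlo estimate of HypE fitness for each row of ``F``."""
    F = np.atleast_2d(np.asarray(F, dtype=float))
    n, m = F.shape
    ideal = F.min(axis=0)
    if reference is None:
        span = F.max(axis=0) - ideal
        reference = F.max(axis=0) + 0.1 * np.where(span > 0, span, 1.0)
    samples = rng.uniform(ideal, reference, size=(n_sample, m))
    dominated = np.all(F[None, :, :] <= samples[:, None, :], axis=2)  # (S, n)
    counts = dominated.sum(axis=1)
    alpha = _alpha(max(k, 1), n)
    weights = np.where(counts > 0, alpha[counts] , 0.0)
    fitness = (dominated * weights[:, None]).sum(axis=0)
    volume = np.prod(reference - ideal)
    return fitness * volume / n_sample


def _environmental(union: list[Individual], size: int,
                   rng: np.random.Generator, n_sample: int
                   ) -> list[Individual]:
    F = np.stack([ind.f for ind in union])
    fronts = nondominated_sort(F)
    chosen: list[int] = []
    for front in fronts:
        if len(chosen) + len(front) <= size:
            chosen.extend(front.tolist())
            continue
        keep = front.tolist()
        while len(chosen) + len(keep) > size:
            k = len(chosen) + len(keep) - size
            fit = hype_fitness(F[keep], k, n_sample, rng)
            worst = int(np.argmin(fit))
            keep.pop(worst)
        chosen.extend(keep)
        break
    return [union[i] for i in chosen]


def _mating_keys(population: list[Individual], n_sample: int,
                 rng: np.random.Generator) -> list:
    F = np.stack([ind.f for ind in population])
    ranks = front_ranks(F)
    fit = hype_fitness(F, k=len(population), n_sample=n_sample, rng=rng)
    return list(zip(ranks.tolist(), (-fit).tolist()))


def run_hype(problem: LatentProblem, params: AlgorithmParams,
             initial: Sequence[Individual], seed: int) -> RunHistory:
    key_rng = np.random.default_rng(seed + 104729)
    return generational_run(
        "hype", problem, params, initial, seed,
        mating_keys=lambda pop: _mating_keys(pop, params.hype_n_sample,
                                             key_rng),
        environmental=lambda union, size, rng:
            _environmental(union, size, rng, params.hype_n_sample))
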