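"""Shared generational scaffolding for the evolutionary algorithms."""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np

from .core import (AlgorithmParams, Individual, LatentProblem, RunHistory,
                   polynomial_mutation, sbx_crossover, tournament_select)

__all__ = ["make_offspring", "generational_run"]


def make_offspring(population: Sequence[Individual], keys: Sequence,
                   n_offspring: int, problem: LatentProblem,
                   params: AlgorithmParams, rng: np.random.Generator
                   ) -> list[Individual]:
    """Binary tournament on ``keys`` (lower better), SBX, polynomial
    mutation, then the decode→evaluate→re-encode repair loop."""
    parents = tournament_select(keys, n_offspring + (n_offspring % 2), rng)
    children = []
    for a, b in zip(parents[::2], parents[1::2]):
        c1, c2 = sbx_crossover(population[a].z, population[b].z,
                               problem.bounds, params.eta_c, params.p_c, rng)
        children.extend([c1, c2])
    children = [polynomial_mutation(c, problem.bounds, params.eta_m,
                                    params.p_m, rng)
                for c in children[:n_offspring]]
    return problem.repair_and_evaluate(np.stack(children))


def generational_run(name: str, problem: LatentProblem,
                     params: AlgorithmParams,
                     initial: Sequence[Individual], seed: int,
                     mating_keys: Callable[[list[Individual]], list],
                     environmental: Callable[[list[Individual], int,
                                              np.random.Generator],
                                             list[Individual]]
                     ) -> RunHistory:
    """Standard (μ+λ) generational loop with strict budget accounting.

    Per generation: ``population_size`` offspring (fewer when the budget is
    nearly spent) from tournament mating, then environmental selection on
    the parent+offspring union.  The history records the population after
    every environmental selection.
    """
    rng = np.random.default_rng(seed)
    history = RunHistory(algorithm=name, seed=seed)
    population = list(initial)
    history.record(population)
    while True:
        n = min(params.population_size, problem.remaining(params))
        if n < 2:
            break
        offspring = make_offspring(population, mating_keys(population), n,
                                   problem, params, rng)
        population = environmental(population + offspring,
                                   len(population), rng)
        history.record(population)
    history.evaluations_used = problem.evaluations
    return history
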