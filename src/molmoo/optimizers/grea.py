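"""Grid-based Evolutionary Algorithm (GrEA).

The objective space of the current population is partitioned into ``div``
divisions per objective (grid bounds padded by half a cell beyond the
population's min/max).  Selection pressure comes from three grid-based
measures: grid ranking GR (sum of grid coordinates — convergence), grid
crowding degree GCD (accumulated penalty for sharing or neighbouring cells
— diversity), and grid coordinate point distance GCPD (distance to the
cell's best corner — fine-grained convergence).  Environmental selection
fills whole Pareto fronts, then picks from the critical front one solution
at a time, punishing the grid ranking of cell-mates and grid-neighbours of
each pick.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .common import generational_run
from .core import (AlgorithmParams, Individual, LatentProblem, RunHistory,
                   front_ranks, nondominated_sort)

__all__ = ["run_grea", "grid_coordinates", "grid_crowding_degrees"]


def grid_setup(F: np.ndarray, div: int):
    fmin = F.min(axis=0)
    fmax = F.max(axis=0)
    span = fmax - fmin
    lb = fmin - span / (2.0 * div)
    width = np.where(span > 0, (span + span / div) / div, 1.0)
    return lb, width


def grid_coordinates(F: np.ndarray, div: int) -> np.ndarray:
    """Integer grid cell per solution (population-adaptive bounds)."""
    lb, width = grid_setup(F, div)
    return np.floor((F - lb) / width).astype(int)


def grid_difference(G: np.ndarray) -> np.ndarray:
    """Pairwise L1 distance between grid coordinates."""
    return np.abs(G[:, None, :] - G[None, :, :]).sum(axis=2)


def grid_crowding_degrees(F: np.ndarray, div: int) -> np.ndarray:
    """GCD over a set: sum over neighbours of (m - grid difference).

    Two solutions in one cell contribute m each to the other — strictly
    more than any pair in different (neighbouring) cells.
    """
    G = grid_coordinates(F, div)
    m = F.shape[1]
    gd = grid_difference(G)
    contrib = np.maximum(0, m - gd)
    np.fill_diagonal(contrib, 0)
    return contrib.sum(axis=1).astype(float)


def _gcpd(F: np.ndarray, div: int) -> np.ndarray:
    lb, width = grid_setup(F, div)
    G = np.floor((F - lb) / width).astype(int)
    return np.sqrt((((F - lb - G * width) / width) ** 2).sum(axis=1))


def _grid_dominates(gq: np.ndarray, gp: np.ndarray) -> bool:
    return bool(np.all(gq <= gp) and np.any(gq < gp))


def _environmental(union: list[Individual], size: int,
                   rng: np.random.Generator, div: int) -> list[Individual]:
    F = np.stack([ind.f for ind in union])
    fronts = nondominated_sort(F)
    chosen: list[int] = []
    for front in fronts:
        if len(chosen) + len(front) <= size:
            chosen.extend(front.tolist())
            continue
        need = size - len(chosen)
        sub = F[front]
        m = sub.shape[1]
        G = grid_coordinates(sub, div)
        gr = G.sum(axis=1).astype(float)
        gcpd = _gcpd(sub, div)
        gcd = np.zeros(len(front))
        remaining = list(range(len(front)))
        picked: list[int] = []
        gdm = grid_difference(G)
        while len(picked) < need:
            best = min(remaining,
                       key=lambda i: (gr[i], gcd[i], gcpd[i],
                                      rng.random()))
            remaining.remove(best)
            picked.append(best)
            for p in remaining:
                diff = gdm[best, p]
                if diff == 0:
                    gr[p] += m + 2
                elif _grid_dominates(G[best], G[p]):
                    gr[p] += m
                elif diff < m:
                    gcd[p] += m - diff
                    gr[p] += m - diff
        chosen.extend(front[picked].tolist())
        break
    return [union[i] for i in chosen]


def _mating_keys(population: list[Individual], div: int) -> list:
    F = np.stack([ind.f for ind in population])
    ranks = front_ranks(F)
    gr = grid_coordinates(F, div).sum(axis=1)
    gcd = grid_crowding_degrees(F, div)
    return list(zip(ranks.tolist(), gr.tolist(), gcd.tolist()))


def run_grea(problem: LatentProblem, params: AlgorithmParams,
             initial: Sequence[Individual], seed: int) -> RunHistory:
    div = params.grea_div
    return generational_run(
        "grea", problem, params, initial, seed,
        mating_keys=lambda pop: _mating_keys(pop, div),
        environmental=lambda union, size, rng:
            _environmental(union, size, rng, div))
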