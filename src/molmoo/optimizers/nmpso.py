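"""NMPSO: many-objective particle swarm with balanceable fitness estimation.

Each particle keeps a personal best; an external archive of mutually
nondominated solutions supplies a global leader and a random archive
leader.  Velocities combine the three guides with per-particle coefficients
redrawn each iteration (omega in [0.1, 0.5], c1..c3 in [1.5, 2.5]).  The
balanceable fitness estimation (BFE) scores a solution by combining a
convergence term (distance of its normalized objective vector from the
ideal point) and a diversity term (shift-based density estimation, SDE);
BFE picks leaders, updates personal bests when dominance is inconclusive,
and truncates the archive.  Polynomial mutation perturbs particles to
escape local optima; positions (not velocities) go through the latent
repair loop.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .core import (AlgorithmParams, Individual, LatentProblem, RunHistory,
                   dominates, nondominated_sort, polynomial_mutation)

__all__ = ["run_nmpso", "balanceable_fitness"]


def balanceable_fitness(F: np.ndarray) -> np.ndarray:
    """BFE score (higher is better): convergence + SDE diversity, both
    normalized to [0, 1] over the set."""
    F = np.atleast_2d(np.asarray(F, dtype=float))
    n = F.shape[0]
    span = F.max(axis=0) - F.min(axis=0)
    FN = (F - F.min(axis=0)) / np.where(span > 0, span, 1.0)
    conv = np.linalg.norm(FN, axis=1)
    conv_score = 1.0 - conv / max(conv.max(), 1e-12)
    if n == 1:
        return np.ones(1)
    shifted = np.maximum(FN[None, :, :] - FN[:, None, :], 0.0)  # (i, j, m)
    sde = np.sqrt((shifted ** 2).sum(axis=2))
    np.fill_diagonal(sde, np.inf)
    density = sde.min(axis=1)
    finite = density[np.isfinite(density)]
    dmax = finite.max() if finite.size else 1.0
    div_score = np.where(np.isfinite(density), density / max(dmax, 1e-12), 1.0)
    return conv_score + div_score


def _truncate_archive(archive: list[Individual], size: int) -> list[Individual]:
    if len(archive) <= size:
        return archive
    F = np.stack([ind.f for ind in archive])
    order = np.argsort(-balanceable_fitness(F))
    return [archive[i] for i in order[:size]]


def run_nmpso(problem: LatentProblem, params: AlgorithmParams,
              initial: Sequence[Individual], seed: int) -> RunHistory:
    rng = np.random.default_rng(seed)
    history = RunHistory(algorithm="nmpso", seed=seed)
    swarm = list(initial)
    N = len(swarm)
    D = problem.dim
    velocity = np.zeros((N, D))
    pbest = list(swarm)
    F0 = np.stack([ind.f for ind in swarm])
    archive = [swarm[i] for i in nondominated_sort(F0)[0]]
    archive = _truncate_archive(archive, N)
    history.record(swarm)
    w_lo, w_hi = params.nmpso_omega
    c_lo, c_hi = params.nmpso_c
    vmax = 0.5 * (problem.bounds.upper - problem.bounds.lower)
    while True:
        n = min(N, problem.remaining(params))
        if n < 1:
            break
        arch_F = np.stack([ind.f for ind in archive])
        gbest = archive[int(np.argmax(balanceable_fitness(arch_F)))]
        positions = np.stack([ind.z for ind in swarm])
        new_positions = positions.copy()
        for i in range(n):
            abest = archive[int(rng.integers(len(archive)))]
            omega = rng.uniform(w_lo, w_hi)
            c1, c2, c3 = rng.uniform(c_lo, c_hi, size=3)
            r1, r2, r3 = rng.random((3, D))
            velocity[i] = (omega * velocity[i]
                           + c1 * r1 * (pbest[i].z - positions[i])
                           + c2 * r2 * (gbest.z - positions[i])
                           + c3 * r3 * (abest.z - positions[i]))
            velocity[i] = np.clip(velocity[i], -vmax, vmax)
            moved = problem.bounds.clip(positions[i] + velocity[i])
            new_positions[i] = polynomial_mutation(
                moved, problem.bounds, params.eta_m, params.p_m, rng)
        evaluated = problem.repair_and_evaluate(new_positions[:n])
        for i, child in enumerate(evaluated):
            swarm[i] = child
            if dominates(child.f, pbest[i].f):
                pbest[i] = child
            elif not dominates(pbest[i].f, child.f):
                pair = np.stack([child.f, pbest[i].f])
                if balanceable_fitness(pair)[0] >= balanceable_fitness(pair)[1]:
                    pbest[i] = child
        merged = archive + evaluated
        FM = np.stack([ind.f for ind in merged])
        # deduplicate identical objective vectors to keep the archive lean
        _, uniq_idx = np.unique(FM, axis=0, return_index=True)
        merged = [merged[i] for i in sorted(uniq_idx)]
        FM = np.stack([ind.f for ind in merged])
        archive = [merged[i] for i in nondominated_sort(FM)[0]]
        archive = _truncate_archive(archive, N)
        history.record(swarm)
    history.evaluations_used = problem.evaluations
    return history
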