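"""A-NSGA-III: reference-point niching with adaptive point relocation.

NSGA-III environmental selection: translate objectives by the (monotone)
ideal point, normalize by intercepts of the hyperplane through the extreme
points found with an achievement scalarizing function, associate every
solution with its nearest reference ray (perpendicular distance), and fill
the critical front by preserving the emptiest niches.  The adaptive variant
additionally inserts, around any reference point whose niche holds two or
more solutions, a small simplex of surrounding points, and deletes inserted
points whose niches have emptied — relocating resolution to crowded parts
of the front.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .common import make_offspring
from .core import (AlgorithmParams, Individual, LatentProblem, RunHistory,
                   front_ranks, nondominated_sort)
from .refpoints import das_dennis, default_reference_points

__all__ = ["run_ansga3", "associate", "normalize_objectives"]


def normalize_objectives(F: np.ndarray, ideal: np.ndarray) -> np.ndarray:
    """Translate by the ideal point and scale by hyperplane intercepts."""
    shifted = F - ideal
    m = F.shape[1]
    # Extreme point per axis: minimizer of the ASF with axis-heavy weights.
    weights = np.full((m, m), 1e-6) + np.eye(m)
    asf = (shifted[None, :, :] / weights[:, None, :]).max(axis=2)  # (m, n)
    extremes = shifted[asf.argmin(axis=1)]
    try:
        intercepts = 1.0 / np.linalg.solve(extremes, np.ones(m))
        if not np.all(np.isfinite(intercepts)) or np.any(intercepts < 1e-12):
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        intercepts = np.maximum(shifted.max(axis=0), 1e-12)
    return shifted / intercepts


def associate(FN: np.ndarray, refs: np.ndarray
              ) -> tuple[np.ndarray, np.ndarray]:
    """Nearest reference ray per solution and the perpendicular distance."""
    R = refs / np.linalg.norm(refs, axis=1, keepdims=True)
    proj = FN @ R.T                                        # (n, r)
    perp = np.linalg.norm(FN[:, None, :] - proj[..., None] * R[None, :, :],
                          axis=2)
    niche = perp.argmin(axis=1)
    return niche, perp[np.arange(FN.shape[0]), niche]


def _niching(front: np.ndarray, niche: np.ndarray, dist: np.ndarray,
             counts: np.ndarray, need: int, rng: np.random.Generator
             ) -> list[int]:
    """NSGA-III niche preservation on the critical front (indices into
    ``front``'s positions)."""
    chosen: list[int] = []
    pool = list(range(len(front)))
    while len(chosen) < need:
        active = {niche[i] for i in pool}
        jmin = min(active, key=lambda j: (counts[j], rng.random()))
        members = [i for i in pool if niche[i] == jmin]
        if counts[jmin] == 0:
            pick = min(members, key=lambda i: dist[i])
        else:
            pick = members[int(rng.integers(len(members)))]
        chosen.append(pick)
        pool.remove(pick)
        counts[jmin] += 1
    return chosen


class _AdaptiveRefs:
    def __init__(self, base: np.ndarray):
        self.base = base
        self.extra = np.empty((0, base.shape[1]))
        # lattice spacing (smallest positive coordinate) sizes the inserted
        # simplices
        positive = base[base > 1e-12]
        self.spacing = float(positive.min()) if positive.size else 0.25

    @property
    def points(self) -> np.ndarray:
        return np.vstack([self.base, self.extra])

    def adapt(self, niche_counts: np.ndarray) -> None:
        """Insert simplices around crowded points; drop empty inserted ones."""
        m = self.base.shape[1]
        if self.extra.size:
            extra_counts = niche_counts[len(self.base):]
            self.extra = self.extra[extra_counts > 0]
        refs = self.points
        crowded = np.flatnonzero(niche_counts[:len(refs)] >= 2)
        new_points = []
        for j in crowded[:len(self.base)]:
            w = refs[j]
            for axis in range(m):
                q = w + 0.5 * self.spacing * (np.eye(m)[axis] - 1.0 / m)
                if np.all(q > -1e-12) and abs(q.sum() - 1.0) < 1e-9:
                    new_points.append(np.clip(q, 0.0, 1.0))
        if new_points:
            candidate = np.vstack([self.extra, *[p[None] for p in new_points]])
            candidate = np.unique(np.round(candidate, 10), axis=0)
            # never duplicate a base point
            keep = [i for i, p in enumerate(candidate)
                    if not np.any(np.all(np.isclose(p, self.base), axis=1))]
            self.extra = candidate[keep][:max(4 * len(self.base), 0)]


def run_ansga3(problem: LatentProblem, params: AlgorithmParams,
               initial: Sequence[Individual], seed: int) -> RunHistory:
    rng = np.random.default_rng(seed)
    history = RunHistory(algorithm="ansga3", seed=seed)
    population = list(initial)
    N = len(population)
    refs = _AdaptiveRefs(default_reference_points(problem.n_objectives, N))
    ideal = np.stack([ind.f for ind in population]).min(axis=0)
    history.record(population)
    while True:
        n = min(params.population_size, problem.remaining(params))
        if n < 2:
            break
        ranks = front_ranks(np.stack([ind.f for ind in population]))
        offspring = make_offspring(population, ranks.tolist(), n, problem,
                                   params, rng)
        union = population + offspring
        F = np.stack([ind.f for ind in union])
        ideal = np.minimum(ideal, F.min(axis=0))   # monotone nonincreasing
        fronts = nondominated_sort(F)
        chosen: list[int] = []
        last_front: np.ndarray | None = None
        for front in fronts:
            if len(chosen) + len(front) <= N:
                chosen.extend(front.tolist())
            else:
                last_front = front
                break
        FN = normalize_objectives(F, ideal)
        refpoints = refs.points
        niche_all, dist_all = associate(FN, refpoints)
        counts = np.bincount(niche_all[chosen], minlength=len(refpoints)) \
            if chosen else np.zeros(len(refpoints), dtype=int)
        if last_front is not None and len(chosen) < N:
            picked = _niching(last_front, niche_all[last_front],
                              dist_all[last_front], counts.copy(),
                              N - len(chosen), rng)
            chosen.extend(last_front[picked].tolist())
        population = [union[i] for i in chosen]
        final_counts = np.bincount(niche_all[chosen], minlength=len(refpoints))
        refs.adapt(final_counts)
        history.record(population)
    history.evaluations_used = problem.evaluations
    return history
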