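"""Shared machinery for latent-space many-objective search.

The decision space is the autoencoder's latent space (or any
:class:`~molmoo.latent.LatentCodec`): an individual is a real vector that
decodes to a molecule.  All algorithms share the real-coded variation
operators of the study — simulated binary crossover (SBX) and polynomial
mutation, both with distribution index 20 — plus Pareto-dominance utilities
and the repair loop: after variation, the offspring vector is decoded, the
decoded molecule is re-encoded, and the re-encoded (clipped) vector replaces
the offspring, so every individual sits at a latent point that actually
represents its molecule.

Search bounds are not part of the model; they are derived per run from the
encoded initial sample (per-dimension min/max expanded by a 10% margin),
keeping the search inside decoder-meaningful territory.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from ..latent import LatentCodec
from ..objectives import ObjectiveRegistry
from ..molecules import canonicalize
from ..selfies_codec import CodecError

__all__ = [
    "Individual",
    "DecisionBounds",
    "AlgorithmParams",
    "GenerationSnapshot",
    "RunHistory",
    "LatentProblem",
    "initialize_population",
    "sbx_crossover",
    "polynomial_mutation",
    "nondominated_sort",
    "dominates",
    "tournament_select",
]


@dataclass
class Individual:
    z: np.ndarray
    smiles: str
    f: np.ndarray


@dataclass(frozen=True)
class DecisionBounds:
    lower: np.ndarray
    upper: np.ndarray

    def __post_init__(self):
        if not np.all(self.lower < self.upper):
            raise ValueError("each lower bound must be below its upper bound")

    @property
    def dim(self) -> int:
        return self.lower.size

    def clip(self, z: np.ndarray) -> np.ndarray:
        return np.clip(z, self.lower, self.upper)

    @classmethod
    def from_sample(cls, points: np.ndarray, margin: float = 0.10
                    ) -> "DecisionBounds":
        lo = points.min(axis=0)
        hi = points.max(axis=0)
        span = np.maximum(hi - lo, 1e-6)
        return cls(lower=lo - margin * span, upper=hi + margin * span)


@dataclass
class AlgorithmParams:
    """Search-budget and operator parameters (defaults are the study's)."""

    population_size: int = 2000
    max_evaluations: int = 25000
    eta_c: float = 20.0
    eta_m: float = 20.0
    p_c: float = 1.0
    p_m: float | None = None  # None -> 1/D
    grea_div: int = 8
    knea_t: float = 0.5
    hype_n_sample: int = 10000
    moeadd_delta: float = 0.9
    moeadd_neighbors: int = 200
    moeadd_theta: float = 5.0
    nmpso_omega: tuple[float, float] = (0.1, 0.5)
    nmpso_c: tuple[float, float] = (1.5, 2.5)

    def __post_init__(self):
        if self.population_size < 2:
            raise ValueError("population size must be at least 2")
        if self.max_evaluations < self.population_size:
            raise ValueError("budget must cover at least one population")


@dataclass
class GenerationSnapshot:
    objectives: np.ndarray        # (n, m) minimization-oriented
    smiles: list[str]

    def nondominated(self) -> np.ndarray:
        fronts = nondominated_sort(self.objectives)
        return self.objectives[fronts[0]]


@dataclass
class RunHistory:
    algorithm: str
    seed: int
    generations: list[GenerationSnapshot] = field(default_factory=list)
    evaluations_used: int = 0

    def record(self, population: Sequence[Individual]) -> None:
        self.generations.append(GenerationSnapshot(
            objectives=np.stack([ind.f for ind in population]),
            smiles=[ind.smiles for ind in population]))

    @property
    def final(self) -> GenerationSnapshot:
        return self.generations[-1]


class LatentProblem:
    """Binds a latent codec, an objective registry, and search bounds."""

    def __init__(self, codec: LatentCodec, registry: ObjectiveRegistry,
                 bounds: DecisionBounds | None = None) -> None:
        self.codec = codec
        self.registry = registry
        self.bounds = bounds
        self.evaluations = 0

    @property
    def n_objectives(self) -> int:
        return len(self.registry)

    @property
    def dim(self) -> int:
        return self.codec.latent_dim

    def repair_and_evaluate(self, Z: np.ndarray) -> list[Individual]:
        """Decode, evaluate and re-encode a batch of latent vectors.

        Every row counts as one function evaluation.  An empty decode keeps
        its (clipped) vector and receives failure-sentinel objectives.
        """
        Z = np.atleast_2d(np.asarray(Z, dtype=float))
        if self.bounds is not None:
            Z = self.bounds.clip(Z)
        smiles = self.codec.decode_latent(Z)
        out: list[Individual] = []
        nonempty = [i for i, s in enumerate(smiles) if s]
        repaired = Z.copy()
        if nonempty:
            try:
                encoded = self.codec.encode_smiles(
                    [smiles[i] for i in nonempty])
                for row, i in enumerate(nonempty):
                    repaired[i] = encoded[row]
            except (ValueError, CodecError):
                # rare: a decoded molecule that cannot be re-encoded (e.g.
                # its SELFIES exceeds the model's sequence budget) keeps
                # its unrepaired vector
                for i in nonempty:
                    try:
                        repaired[i] = self.codec.encode_smiles([smiles[i]])[0]
                    except (ValueError, CodecError):
                        pass
            if self.bounds is not None:
                repaired = self.bounds.clip(repaired)
        for i, smi in enumerate(smiles):
            vec = self.registry.evaluate(smi)
            out.append(Individual(z=repaired[i], smiles=smi,
                                  f=vec.as_array()))
        self.evaluations += len(smiles)
        return out

    def remaining(self, params: AlgorithmParams) -> int:
        return max(0, params.max_evaluations - self.evaluations)


class InitializationError(ValueError):
    pass


def initialize_population(dataset: Sequence[str], problem: LatentProblem,
                          size: int, seed: int,
                          bounds_margin: float = 0.10) -> list[Individual]:
    """Seeded sample (without replacement) from the dataset, encoded and
    evaluated; derives the problem's decision bounds from the encoded sample."""
    unique = sorted({canonicalize(s) for s in dataset})
    if len(unique) < size:
        raise InitializationError(
            f"dataset has {len(unique)} unique molecules, need {size}")
    rng = np.random.default_rng(seed)
    chosen = [unique[i] for i in rng.choice(len(unique), size=size,
                                            replace=False)]
    Z = problem.codec.encode_smiles(chosen)
    problem.bounds = DecisionBounds.from_sample(Z, margin=bounds_margin)
    population = []
    for smi, z in zip(chosen, Z):
        vec = problem.registry.evaluate(smi)
        population.append(Individual(z=problem.bounds.clip(z), smiles=smi,
                                     f=vec.as_array()))
    problem.evaluations += size
    return population


# ---------------------------------------------------------------------------
# Variation operators
# ---------------------------------------------------------------------------

def sbx_crossover(p1: np.ndarray, p2: np.ndarray, bounds: DecisionBounds,
                  eta_c: float = 20.0, p_c: float = 1.0,
                  rng: np.random.Generator | None = None
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Simulated binary crossover (distribution index ``eta_c``).

    With the per-variable uniform draw u = 0.5 the spread factor is exactly
    1 and the offspring equal the parents.  Offspring are clipped to bounds.
    """
    rng = rng or np.random.default_rng()
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    if p_c < 1.0 and rng.random() > p_c:
        return p1.copy(), p2.copy()
    u = rng.random(p1.size)
    beta = np.where(u <= 0.5,
                    (2.0 * u) ** (1.0 / (eta_c + 1.0)),
                    (1.0 / (2.0 * (1.0 - u))) ** (1.0 / (eta_c + 1.0)))
    c1 = 0.5 * ((1 + beta) * p1 + (1 - beta) * p2)
    c2 = 0.5 * ((1 - beta) * p1 + (1 + beta) * p2)
    return bounds.clip(c1), bounds.clip(c2)


def polynomial_mutation(z: np.ndarray, bounds: DecisionBounds,
                        eta_m: float = 20.0, p_m: float | None = None,
                        rng: np.random.Generator | None = None) -> np.ndarray:
    """Bounded polynomial mutation (distribution index ``eta_m``).

    Each variable mutates with probability ``p_m`` (default 1/D); the draw
    u = 0.5 maps to a zero perturbation.
    """
    rng = rng or np.random.default_rng()
    z = np.asarray(z, dtype=float)
    D = z.size
    if p_m is None:
        p_m = 1.0 / D
    gate = rng.random(D) < p_m
    u = rng.random(D)
    lo, hi = bounds.lower, bounds.upper
    span = hi - lo
    d1 = (z - lo) / span
    d2 = (hi - z) / span
    exp = 1.0 / (eta_m + 1.0)
    low_branch = (2.0 * u + (1.0 - 2.0 * u) * (1.0 - d1) ** (eta_m + 1.0)) ** exp - 1.0
    high_branch = 1.0 - (2.0 * (1.0 - u)
                         + 2.0 * (u - 0.5) * (1.0 - d2) ** (eta_m + 1.0)) ** exp
    delta = np.where(u < 0.5, low_branch, high_branch)
    out = np.where(gate, z + delta * span, z)
    return bounds.clip(out)


# ---------------------------------------------------------------------------
# Dominance machinery
# ---------------------------------------------------------------------------

def dominates(a: np.ndarray, b: np.ndarray) -> bool:
    """Pareto dominance under minimization."""
    return bool(np.all(a <= b) and np.any(a < b))


def nondominated_sort(F: np.ndarray) -> list[np.ndarray]:
    """Fast non-dominated sort: fronts as index arrays, best first."""
    F = np.asarray(F, dtype=float)
    n = F.shape[0]
    # Pairwise dominance matrix, vectorized: dom[i, j] = i dominates j.
    le = np.all(F[:, None, :] <= F[None, :, :], axis=2)
    lt = np.any(F[:, None, :] < F[None, :, :], axis=2)
    dom = le & lt
    counts = dom.sum(axis=0).astype(int)   # number of dominators per point
    dominated_by = [np.flatnonzero(dom[i]) for i in range(n)]
    fronts = []
    current = np.flatnonzero(counts == 0)
    counts[current] = -1
    while current.size:
        fronts.append(current)
        for i in current:
            counts[dominated_by[i]] -= 1
        nxt = np.flatnonzero(counts == 0)
        counts[nxt] = -1
        current = nxt
    return fronts


def front_ranks(F: np.ndarray) -> np.ndarray:
    """Per-solution front index (0 = nondominated)."""
    ranks = np.empty(F.shape[0], dtype=int)
    for k, front in enumerate(nondominated_sort(F)):
        ranks[front] = k
    return ranks


def tournament_select(keys: Sequence, n_picks: int,
                      rng: np.random.Generator) -> list[int]:
    """Binary tournament on sortable fitness keys (lower is better)."""
    n = len(keys)
    picks = []
    for _ in range(n_picks):
        i, j = rng.integers(0, n, size=2)
        picks.append(int(i) if keys[int(i)] <= keys[int(j)] else int(j))
    return picks
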