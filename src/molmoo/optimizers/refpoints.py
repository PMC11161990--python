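"""Das–Dennis simplex-lattice reference/weight vectors.

Systematic construction: all nonnegative integer compositions of H into m
parts, divided by H, giving points on the unit simplex.  For many
objectives a single layer either explodes combinatorially or is too coarse,
so a two-layer variant places a boundary layer and a shrunken inner layer
(the inner points pulled halfway toward the simplex centre), which keeps
the count near the population size at six objectives.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np

__all__ = ["das_dennis", "two_layer", "default_reference_points"]


def das_dennis(m: int, h: int) -> np.ndarray:
    """All points p on the unit m-simplex with coordinates multiples of 1/h."""
    if m < 2:
        raise ValueError("need at least two objectives")
    out = []
    for dividers in combinations(range(h + m - 1), m - 1):
        prev = -1
        coords = []
        for d in dividers:
            coords.append(d - prev - 1)
            prev = d
        coords.append(h + m - 2 - prev)
        out.append(coords)
    return np.asarray(out, dtype=float) / h


def two_layer(m: int, h_boundary: int, h_inner: int) -> np.ndarray:
    """Boundary layer plus an inner layer shrunk toward the centroid."""
    boundary = das_dennis(m, h_boundary)
    inner = das_dennis(m, h_inner) * 0.5 + 0.5 / m
    points = np.vstack([boundary, inner])
    return np.unique(np.round(points, 12), axis=0)


def default_reference_points(m: int, population_size: int) -> np.ndarray:
    """A sensible lattice for ``m`` objectives sized near the population.

    Uses the largest single-layer lattice that stays at or below the
    population size for few objectives; from five objectives on, the
    two-layer construction (boundary H=3, inner H=2) keeps counts moderate.
    """
    if m <= 4:
        h = 1
        while len(das_dennis(m, h + 1)) <= max(population_size, m + 1):
            h += 1
        return das_dennis(m, h)
    return two_layer(m, 3, 2)
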