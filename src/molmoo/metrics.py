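"""Optimization-quality metrics and run reports.

Since the true Pareto front of a molecular design problem is unknown, the
reference front is approximated by the dominance-filtered union of all final
(or per-generation) populations across every run and algorithm; GD and IGD
are then mean nearest-neighbour Euclidean distances between an approximation
set and that reference.  Population-level chemistry metrics — uniqueness
(distinct canonical SMILES fraction) and novelty (fraction absent from the
training set) — and per-objective 1-Wasserstein distances between initial
and final populations complete the panel.  Objective vectors are compared
unnormalized by default (configurable).
"""

from __future__ import annotations

import os
from typing import Iterable, Sequence

import numpy as np
from scipy.stats import wasserstein_distance

from .molecules import canonicalize
from .optimizers.core import GenerationSnapshot, RunHistory, nondominated_sort

__all__ = [
    "gd", "igd", "build_reference_front", "uniqueness", "novelty",
    "wasserstein_1d", "exact_hypervolume", "make_report",
]


def _min_distances(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """For each row of A, Euclidean distance to the nearest row of B."""
    diff = A[:, None, :] - B[None, :, :]
    return np.sqrt((diff ** 2).sum(axis=2)).min(axis=1)


def _check_fronts(A, R) -> tuple[np.ndarray, np.ndarray]:
    A = np.atleast_2d(np.asarray(A, dtype=float))
    R = np.atleast_2d(np.asarray(R, dtype=float))
    if A.size == 0 or R.size == 0:
        raise ValueError("fronts must be nonempty")
    if A.shape[1] != R.shape[1]:
        raise ValueError("objective counts differ")
    return A, R


def gd(front: np.ndarray, reference: np.ndarray) -> float:
    """Generational distance: mean distance from ``front`` to ``reference``."""
    A, R = _check_fronts(front, reference)
    return float(_min_distances(A, R).mean())


def igd(front: np.ndarray, reference: np.ndarray) -> float:
    """Inverted generational distance: mean distance from the reference
    points to the approximation front (== gd with arguments swapped)."""
    A, R = _check_fronts(front, reference)
    return float(_min_distances(R, A).mean())


def build_reference_front(histories: Sequence[RunHistory],
                          final_only: bool = True) -> np.ndarray:
    """Nondominated union of objective vectors across runs (deduplicated)."""
    if not histories:
        raise ValueError("need at least one run history")
    blocks = []
    for hist in histories:
        snaps = [hist.final] if final_only else hist.generations
        blocks.extend(s.objectives for s in snaps)
    merged = np.unique(np.vstack(blocks), axis=0)
    fronts = nondominated_sort(merged)
    return merged[fronts[0]]


def uniqueness(population_smiles: Sequence[str]) -> float:
    """Fraction of distinct canonical SMILES in a population."""
    if not population_smiles:
        raise ValueError("empty population")
    canon = [canonicalize(s) if s else "" for s in population_smiles]
    return len(set(canon)) / len(canon)


def novelty(population_smiles: Sequence[str],
            training_smiles: Iterable[str]) -> float:
    """Fraction of the population absent from the training set."""
    if not population_smiles:
        raise ValueError("empty population")
    train = {canonicalize(s) for s in training_smiles}
    canon = [canonicalize(s) if s else "" for s in population_smiles]
    return sum(1 for c in canon if c not in train) / len(canon)


def wasserstein_1d(p: Sequence[float], q: Sequence[float]) -> float:
    """1-Wasserstein (earth mover) distance between 1D samples."""
    return float(wasserstein_distance(np.asarray(p, float),
                                      np.asarray(q, float)))


def exact_hypervolume(points: np.ndarray, reference: np.ndarray) -> float:
    """Exact dominated hypervolume for 2–3 objectives (oracle scale, ≤ a few
    dozen points), via coordinate sweeps.

    Points at or beyond the reference contribute nothing.  Used as the
    independent check of HypE's Monte Carlo contribution estimates.
    """
    P = np.atleast_2d(np.asarray(points, dtype=float))
    r = np.asarray(reference, dtype=float)
    m = r.size
    if P.shape[1] != m:
        raise ValueError("dimension mismatch")
    P = P[np.all(P < r, axis=1)]
    if P.size == 0:
        return 0.0
    if m == 1:
        return float(r[0] - P[:, 0].min())
    if m == 2:
        # Sweep points by first objective; accumulate staircase area.
        order = np.argsort(P[:, 0])
        area = 0.0
        best_y = r[1]
        for i in order:
            x, y = P[i]
            if y < best_y:
                area += (r[0] - x) * (best_y - y)
                best_y = y
        return float(area)
    if m == 3:
        # Slice along the third objective: between consecutive z-levels the
        # dominated cross-section is the 2D hypervolume of points below.
        zs = np.unique(P[:, 2])
        volume = 0.0
        levels = np.append(zs, r[2])
        for k, z in enumerate(zs):
            depth = levels[k + 1] - z
            active = P[P[:, 2] <= z][:, :2]
            volume += depth * exact_hypervolume(active, r[:2])
        return float(volume)
    raise ValueError("exact hypervolume oracle supports at most 3 objectives")


def make_report(histories: Sequence[RunHistory], training_smiles: Sequence[str],
                out_dir: str, objective_names: Sequence[str] | None = None,
                reference: np.ndarray | None = None) -> dict:
    """Aggregate metric curves and distribution plots across runs.

    Per generation and run: GD, IGD (against the cross-run reference front),
    uniqueness and novelty; curves are written per algorithm with mean ±
    standard deviation across seeds.  Final vs initial per-objective kernel
    density plots are annotated with 1-Wasserstein distances and best
    values.  Returns the report dictionary (the same numbers the CSVs and
    plots contain).
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import pandas as pd

    if not histories:
        raise ValueError("no histories to report on")
    os.makedirs(out_dir, exist_ok=True)
    if reference is None:
        reference = build_reference_front(histories)
    m = histories[0].final.objectives.shape[1]
    names = list(objective_names) if objective_names else \
        [f"f{k}" for k in range(m)]

    rows = []
    for hist in histories:
        for g, snap in enumerate(hist.generations):
            front = snap.nondominated()
            rows.append({
                "algorithm": hist.algorithm, "seed": hist.seed,
                "generation": g,
                "gd": gd(front, reference), "igd": igd(front, reference),
                "uniqueness": uniqueness(snap.smiles),
                "novelty": novelty(snap.smiles, training_smiles)})
    curves = pd.DataFrame(rows)
    curves.to_csv(os.path.join(out_dir, "metric_curves.csv"), index=False)

    for metric in ("gd", "igd", "uniqueness", "novelty"):
        fig, ax = plt.subplots(figsize=(5.5, 4))
        for algorithm, block in curves.groupby("algorithm"):
            stats = block.groupby("generation")[metric].agg(["mean", "std"])
            std = stats["std"].fillna(0.0)
            ax.plot(stats.index, stats["mean"], label=algorithm)
            ax.fill_between(stats.index, stats["mean"] - std,
                            stats["mean"] + std, alpha=0.2)
        ax.set_xlabel("generation")
        ax.set_ylabel(metric)
        ax.legend(fontsize=7)
        fig.tight_layout()
        fig.savefig(os.path.join(out_dir, f"curve_{metric}.png"), dpi=120)
        plt.close(fig)

    initial = np.vstack([h.generations[0].objectives for h in histories])
    final = np.vstack([h.final.objectives for h in histories])
    distances = {}
    best = {}
    for k, name in enumerate(names):
        distances[name] = wasserstein_1d(initial[:, k], final[:, k])
        best[name] = {"initial": float(initial[:, k].min()),
                      "final": float(final[:, k].min())}
        fig, ax = plt.subplots(figsize=(5, 3.5))
        for label, sample in (("initial", initial[:, k]), ("final", final[:, k])):
            if np.std(sample) > 1e-12:
                from scipy.stats import gaussian_kde
                grid = np.linspace(sample.min(), sample.max(), 200)
                ax.plot(grid, gaussian_kde(sample)(grid), label=label)
            else:
                ax.axvline(sample[0], label=label)
        ax.set_title(f"{name} — W1 = {distances[name]:.3g}")
        ax.legend(fontsize=8)
        fig.tight_layout()
        fig.savefig(os.path.join(out_dir, f"density_{name}.png"), dpi=120)
        plt.close(fig)

    report = {"curves": curves, "wasserstein": distances,
              "best_values": best, "reference_size": int(len(reference))}
    pd.DataFrame([{"objective": n, "wasserstein": distances[n],
                   "best_initial": best[n]["initial"],
                   "best_final": best[n]["final"]} for n in names]
                 ).to_csv(os.path.join(out_dir, "summary.csv"), index=False)
    return report
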