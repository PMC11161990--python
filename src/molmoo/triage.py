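"""Candidate triage: filters plus normalized sum-of-ranks ordering.

After optimization, final populations are filtered for drug-likeness
(Ghose lipophilicity window −0.4 ≤ logP ≤ 5.6), binding affinity
(≤ −7.1 kcal/mol, the weakest score among known reference inhibitors) and
synthesizability (SAS ≤ 3).  Survivors are ordered by a normalized sum of
ranks: per objective, rank candidates best-first on the
minimization-oriented value (ties get average ranks), divide each rank by
the candidate count, and sum across objectives — lower scores are better,
and the ordering is invariant to any monotone rescaling of an objective.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = ["FilterSpec", "apply_filters", "rank_sum_of_ranks", "export_top_k"]


@dataclass(frozen=True)
class FilterSpec:
    logp_window: tuple[float, float] = (-0.4, 5.6)
    binding_max: float = -7.1
    sas_max: float = 3.0

    def __post_init__(self):
        if self.logp_window[0] >= self.logp_window[1]:
            raise ValueError("logP window must have lower < upper")


REQUIRED_COLUMNS = ("smiles", "logP", "SAS", "binding")


def apply_filters(candidates: pd.DataFrame, spec: FilterSpec | None = None
                  ) -> tuple[pd.DataFrame, dict[str, int]]:
    """Conjunction of the Ghose, binding and SAS filters (inclusive bounds).

    ``candidates`` needs columns smiles/logP/SAS/binding; rows missing any
    required value are excluded and counted under ``missing_values``.
    Returns (survivors with original columns, per-filter pass counts).
    """
    spec = spec or FilterSpec()
    missing_cols = [c for c in REQUIRED_COLUMNS if c not in candidates.columns]
    if missing_cols:
        raise KeyError(f"candidate table lacks columns {missing_cols}")
    usable = candidates.dropna(subset=list(REQUIRED_COLUMNS))
    lo, hi = spec.logp_window
    ghose = usable["logP"].between(lo, hi)
    binding = usable["binding"] <= spec.binding_max
    sas = usable["SAS"] <= spec.sas_max
    survivors = usable[ghose & binding & sas]
    counts = {
        "input": int(len(candidates)),
        "missing_values": int(len(candidates) - len(usable)),
        "pass_ghose": int(ghose.sum()),
        "pass_binding": int(binding.sum()),
        "pass_sas": int(sas.sum()),
        "survivors": int(len(survivors)),
    }
    return survivors.copy(), counts


def rank_sum_of_ranks(candidates: pd.DataFrame,
                      objective_columns: list[str]) -> pd.DataFrame:
    """Order candidates by normalized sum of ranks (ascending = better).

    Objective columns must be minimization-oriented.  Ranks are averaged
    over ties and normalized by the candidate count; exact score ties are
    broken deterministically by canonical SMILES.
    """
    if candidates.empty:
        raise ValueError("no candidates to rank")
    n = len(candidates)
    out = candidates.copy()
    total = np.zeros(n)
    for col in objective_columns:
        total += rankdata(out[col].to_numpy(), method="average") / n
    out["rank_score"] = total
    out = out.sort_values(["rank_score", "smiles"], kind="mergesort")
    out["rank"] = np.arange(1, n + 1)
    return out.reset_index(drop=True)


def export_top_k(ranked: pd.DataFrame, k: int = 25,
                 csv_path: str | None = None,
                 image_path: str | None = None) -> pd.DataFrame:
    """Unique top-k candidates, optional CSV and 2D-structure grid image.

    Deduplicates by canonical SMILES (keeping each molecule's best rank)
    before the cutoff; warns when fewer than ``k`` unique survivors exist.
    """
    import warnings
    if k < 1:
        raise ValueError("k must be >= 1")
    unique = ranked.drop_duplicates(subset="smiles", keep="first")
    if len(unique) < k:
        warnings.warn(f"only {len(unique)} unique candidates for top-{k}")
    top = unique.head(k).reset_index(drop=True)
    if csv_path:
        top.to_csv(csv_path, index=False)
    if image_path:
        from rdkit import Chem
        from rdkit.Chem import Draw
        mols = [Chem.MolFromSmiles(s) for s in top["smiles"]]
        legends = [f"#{int(r)} {s:.3f}" for r, s in
                   zip(top["rank"], top["rank_score"])]
        img = Draw.MolsToGridImage(mols, molsPerRow=5, legends=legends,
                                   subImgSize=(200, 160))
        with open(image_path, "wb") as fh:
            if hasattr(img, "data"):
                fh.write(img.data)
            else:
                img.save(fh)
    return top
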