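"""Seeded generators of small, diverse, valid molecule sets and toy problems.

Real training corpora (millions of ZINC/ChEMBL/MOSES molecules) are out of
reach for desk-scale work, so every stage of the system is exercised on
grammar-assembled fixtures: a scaffold (alkane chain, aromatic or
heteroaromatic ring, amide, sulfonamide) is decorated with substituents drawn
from a small fragment pool.  Assembly is deterministic per seed, every
product is RDKit-valid and charge-free (hence codec-compatible), and the
families are chosen so that logP/SAS/QED spread widely enough to give the
objective space real Pareto structure.  No attempt is made to mimic the
property distributions of real screening libraries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem

from .latent import DescriptorCodec, LatentCodec
from .molecules import canonicalize, compute_properties
from .objectives import (ObjectiveRegistry, ObjectiveSpec, surrogate_admet,
                         SURROGATE_DIRECTIONS)
from .optimizers.core import LatentProblem
from .selfies_codec import CodecError

__all__ = ["FixtureSpec", "FixtureError", "generate_molecules", "toy_problem"]

SCAFFOLD_FAMILIES = ("alkanes", "aromatics", "heteroaromatics", "amides",
                     "sulfonamides")


class FixtureError(RuntimeError):
    """Requested number of distinct molecules could not be assembled."""


@dataclass(frozen=True)
class FixtureSpec:
    n_molecules: int = 100
    families: tuple[str, ...] = SCAFFOLD_FAMILIES
    decoration_rate: float = 0.7
    seed: int = 0

    def __post_init__(self):
        if self.n_molecules < 1:
            raise ValueError("n_molecules must be >= 1")
        unknown = set(self.families) - set(SCAFFOLD_FAMILIES)
        if unknown:
            raise ValueError(f"unknown scaffold families: {sorted(unknown)}")
        if not 0.0 <= self.decoration_rate <= 1.0:
            raise ValueError("decoration_rate must be in [0, 1]")


# Substituents valid inside a '(...)' branch or appended to a chain.
_SUBSTITUENTS = ("C", "CC", "CCC", "C(C)C", "O", "OC", "N", "N(C)C", "F",
                 "Cl", "Br", "C#N", "C(F)(F)F", "CO", "OCC", "C=C",
                 "C(=O)O", "C(=O)N", "S(C)(=O)=O", "c1ccccc1")

# Ring templates with optional substitution slots {a}/{b}; empty slots are
# removed together with their parentheses.
_RING_TEMPLATES = {
    "aromatics": ("c1ccc({a})cc1", "c1ccc({a})c({b})c1", "c1cc({a})cc({b})c1",
                  "c1ccc2ccccc2c1", "c1ccc({a})cc1{b}"),
    "heteroaromatics": ("c1ccnc({a})c1", "c1cc({a})ncn1", "c1cc({a})oc1",
                        "c1cc({a})sc1", "c1cc({a})[nH]c1", "c1cnc2[nH]ccc2c1",
                        "c1ccc2ncccc2c1"),
}


def _fill_ring(template: str, rng: np.random.Generator, rate: float) -> str:
    out = template
    for slot in ("{a}", "{b}"):
        wrapped = f"({slot})"
        if slot not in out:
            continue
        if rng.random() < rate:
            sub = _SUBSTITUENTS[rng.integers(len(_SUBSTITUENTS))]
            out = out.replace(wrapped, f"({sub})").replace(slot, sub)
        else:
            out = out.replace(wrapped, "").replace(slot, "")
    return out


def _alkane(rng: np.random.Generator, rate: float) -> str:
    length = int(rng.integers(2, 12))
    atoms = ["C"] * length
    smi = ""
    for i, a in enumerate(atoms):
        smi += a
        if 0 < i < length - 1 and rng.random() < 0.3 * rate:
            smi += "(C)"
    if rng.random() < rate:  # polar terminus widens the property spread
        smi += rng.choice(["O", "N", "C(=O)O", ""])
    return smi


def _aryl_or_alkyl(rng: np.random.Generator, rate: float) -> str:
    if rng.random() < 0.5:
        return _fill_ring(_RING_TEMPLATES["aromatics"][
            rng.integers(len(_RING_TEMPLATES["aromatics"]))], rng, rate)
    return "C" * int(rng.integers(1, 5))


def _assemble(family: str, rng: np.random.Generator, rate: float) -> str:
    if family == "alkanes":
        return _alkane(rng, rate)
    if family in ("aromatics", "heteroaromatics"):
        templates = _RING_TEMPLATES[family]
        return _fill_ring(templates[rng.integers(len(templates))], rng, rate)
    if family == "amides":
        return f"{_aryl_or_alkyl(rng, rate)}C(=O)N{_aryl_or_alkyl(rng, rate)}"
    if family == "sulfonamides":
        return f"{_aryl_or_alkyl(rng, rate)}S(=O)(=O)N{_aryl_or_alkyl(rng, rate)}"
    raise ValueError(family)


def generate_molecules(spec: FixtureSpec) -> list[str]:
    """Distinct, valid, canonical SMILES per the fixture spec.

    Deterministic per seed.  Raises :class:`FixtureError` if the requested
    count cannot be assembled (the grammar supports a few thousand distinct
    products under the default spec).
    """
    rng = np.random.default_rng(spec.seed)
    seen: dict[str, None] = {}
    attempts = 0
    max_attempts = 400 * spec.n_molecules + 1000
    families = list(spec.families)
    while len(seen) < spec.n_molecules:
        attempts += 1
        if attempts > max_attempts:
            raise FixtureError(
                f"could not assemble {spec.n_molecules} distinct molecules "
                f"(got {len(seen)})")
        family = families[rng.integers(len(families))]
        smi = _assemble(family, rng, spec.decoration_rate)
        mol = Chem.MolFromSmiles(smi)
        if mol is None:
            continue
        # Products are neutral organic-subset molecules by construction,
        # hence codec-compatible; one parse + canonical write per candidate.
        seen.setdefault(Chem.MolToSmiles(mol), None)
    return list(seen)


# ---------------------------------------------------------------------------
# Toy optimization problem
# ---------------------------------------------------------------------------

def _logp_window_distance(smiles: str) -> float:
    """Distance of logP from the drug-like window [-0.4, 5.6] (0 inside)."""
    logp = compute_properties(smiles)["logP"]
    if logp < -0.4:
        return -0.4 - logp
    if logp > 5.6:
        return logp - 5.6
    return 0.0


def _heavy_atoms(smiles: str) -> float:
    return float(Chem.MolFromSmiles(smiles).GetNumHeavyAtoms())


def toy_problem(m_objectives: int = 4, codec: LatentCodec | None = None,
                library: list[str] | None = None,
                seed: int = 0) -> LatentProblem:
    """Desk-scale many-objective problem over locally computable objectives.

    The first four objectives are QED (maximized), SAS, distance of logP
    from the drug-like window, and heavy-atom count (all minimized);
    additional objectives are drawn from the synthetic ADMET surrogate with
    the orientations of the full drug-design panel.  If no codec is given,
    a :class:`DescriptorCodec` identity embedding is built over ``library``
    (generated from the default fixture spec when absent).
    """
    if m_objectives < 2:
        raise ValueError("need at least two objectives")
    base = [
        ObjectiveSpec("qed", "maximize",
                      lambda s: compute_properties(s)["QED"], 0.0),
        ObjectiveSpec("sas", "minimize",
                      lambda s: compute_properties(s)["SAS"], 10.0),
        ObjectiveSpec("logp_window", "minimize", _logp_window_distance, 100.0),
        ObjectiveSpec("heavy_atoms", "minimize", _heavy_atoms, 1000.0),
    ]
    extra_names = [n for n in SURROGATE_DIRECTIONS if n != "sas"]
    for name in extra_names:
        direction = SURROGATE_DIRECTIONS[name]
        base.append(ObjectiveSpec(
            name, direction,
            (lambda key: lambda s: surrogate_admet(s)[key])(name),
            -1e6 if direction == "maximize" else 1e6))
    if m_objectives > len(base):
        raise ValueError(f"at most {len(base)} objectives available")
    registry = ObjectiveRegistry(base[:m_objectives])
    if codec is None:
        if library is None:
            library = generate_molecules(FixtureSpec(n_molecules=400, seed=seed))
        codec = DescriptorCodec(library)
    return LatentProblem(codec=codec, registry=registry)
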