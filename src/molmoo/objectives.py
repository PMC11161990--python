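"""Objective registry: molecule -> minimization-oriented objective vector.

The drug-design search scores each decoded molecule on a panel of
objectives — binding affinity, synthetic accessibility (SAS), and ADMET
endpoints such as bioavailability, solubility, acute toxicity LD50 and
clinical-trial toxicity.  Objectives declared as maximization are negated on
the way in, so the optimizers always minimize; reports negate back for
display.  Evaluations are cached by canonical SMILES, and evaluator failures
are replaced by each objective's declared worst-case sentinel so that failed
molecules lose dominance comparisons instead of crashing the run.

External predictors (a docking engine, a trained ADMET model) are consumed
through adapters.  ``surrogate_admet`` is a synthetic, deterministic
descriptor-based stand-in exposing the same six objective names and
orientations, so the whole system runs offline.
"""

from __future__ import annotations

import math
import shutil
import subprocess
import tempfile
import os
import re
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem import Crippen, Descriptors, rdMolDescriptors

from .molecules import canonicalize, compute_properties
from .selfies_codec import CodecError

__all__ = [
    "ObjectiveSpec",
    "ObjectiveRegistry",
    "ObjectiveVector",
    "DockingConfig",
    "DockingUnavailableError",
    "surrogate_admet",
    "docking_adapter",
    "build_registry",
    "default_surrogate_registry",
]

#: Sentinel recorded when docking fails for a molecule (already worst-case
#: on the minimization scale).
INVALID_DOCKING_VALUE = 1_000_000.0


class DockingUnavailableError(RuntimeError):
    """No docking executable configured: desk runs must use the surrogate."""


@dataclass(frozen=True)
class DockingConfig:
    """Search-box parameters for the docking adapter (LPA1 defaults)."""

    center: tuple[float, float, float] = (14.444, 5.250, -18.278)
    size: tuple[float, float, float] = (20.0, 20.0, 20.0)
    invalid_docking_value: float = INVALID_DOCKING_VALUE
    receptor_path: str | None = None
    executable: str | None = None

    def __post_init__(self):
        if any(s <= 0 for s in self.size):
            raise ValueError("docking box sizes must be positive")


@dataclass(frozen=True)
class ObjectiveSpec:
    """One objective: name, optimization direction, evaluator, failure value.

    ``failure_value`` is on the evaluator's natural scale and must be
    worst-case under ``direction`` (it is checked to be so after the
    orientation flip).
    """

    name: str
    direction: str  # "minimize" | "maximize"
    evaluator: Callable[[str], float]
    failure_value: float

    def __post_init__(self):
        if self.direction not in ("minimize", "maximize"):
            raise ValueError(f"bad direction {self.direction!r}")

    def oriented(self, value: float) -> float:
        return -value if self.direction == "maximize" else value


@dataclass(frozen=True)
class ObjectiveVector:
    values: tuple[float, ...]
    evaluated_on: str

    def __len__(self) -> int:
        return len(self.values)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.values, dtype=float)


class ObjectiveRegistry:
    """Ordered, uniquely named objective panel with per-molecule caching."""

    def __init__(self, specs: Sequence[ObjectiveSpec]) -> None:
        if not specs:
            raise ValueError("registry must contain at least one objective")
        names = [s.name for s in specs]
        if len(set(names)) != len(names):
            raise ValueError("objective names must be unique")
        self.specs = list(specs)
        self._cache: dict[str, ObjectiveVector] = {}
        self.backend_calls = 0

    @property
    def names(self) -> list[str]:
        return [s.name for s in self.specs]

    @property
    def directions(self) -> list[str]:
        return [s.direction for s in self.specs]

    def __len__(self) -> int:
        return len(self.specs)

    def evaluate(self, smiles: str) -> ObjectiveVector:
        """Minimization-oriented objective vector, cached by canonical SMILES.

        An empty SMILES (the empty-molecule decode sentinel) and evaluator
        crashes both map to the per-objective failure sentinels.
        """
        if smiles == "":
            return ObjectiveVector(
                tuple(s.oriented(s.failure_value) for s in self.specs), "")
        key = canonicalize(smiles)
        if key in self._cache:
            return self._cache[key]
        self.backend_calls += 1
        values = []
        for spec in self.specs:
            try:
                raw = float(spec.evaluator(key))
                if not math.isfinite(raw):
                    raw = spec.failure_value
            except Exception:
                raw = spec.failure_value
            values.append(spec.oriented(raw))
        vec = ObjectiveVector(tuple(values), key)
        self._cache[key] = vec
        return vec

    def to_display(self, oriented: np.ndarray) -> np.ndarray:
        """Convert minimization-oriented values back to each objective's
        natural scale (undo the negation of maximization objectives)."""
        signs = np.array([-1.0 if d == "maximize" else 1.0
                          for d in self.directions])
        return np.asarray(oriented, dtype=float) * signs


# ---------------------------------------------------------------------------
# Synthetic ADMET surrogate (deterministic stand-in for a trained predictor)
# ---------------------------------------------------------------------------

def surrogate_admet(smiles: str) -> dict[str, float]:
    """Synthetic, deterministic ADMET-style predictions from descriptors.

    Smooth functions of RDKit descriptors shaped to the orientation and
    rough scale of the six drug-design objectives.  This is a test/desk
    stand-in, not a trained predictor: values are reproducible and finite
    for any parseable molecule, and drug-like molecules score better than
    extreme ones, but no pharmacological accuracy is claimed.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise CodecError(f"unparseable SMILES: {smiles!r}")
    logp = Crippen.MolLogP(mol)
    mw = Descriptors.MolWt(mol)
    tpsa = rdMolDescriptors.CalcTPSA(mol)
    heavy = mol.GetNumHeavyAtoms()
    rot = rdMolDescriptors.CalcNumRotatableBonds(mol)
    arom = rdMolDescriptors.CalcNumAromaticRings(mol)
    props = compute_properties(smiles)

    def logistic(x: float) -> float:
        return 1.0 / (1.0 + math.exp(-max(-60.0, min(60.0, x))))

    # Oral bioavailability in (0, 1): best near logP ~ 2 and moderate TPSA.
    bioavailability = logistic(2.0 - 0.25 * (logp - 2.0) ** 2 - 0.02 * abs(tpsa - 75.0))
    # ESOL-style aqueous solubility (log mol/L): decreases with lipophilicity
    # and size, increases with polar surface area.
    solubility = 0.16 - 0.63 * logp - 0.0062 * mw + 0.066 * rot \
        - 0.005 * tpsa - 0.2 * arom
    # Acute toxicity LD50 surrogate: affine in heavy-atom count and logP
    # (larger/more lipophilic molecules trend more toxic here).
    ld50 = -1.0 + 0.04 * heavy + 0.15 * logp
    # Clinical-toxicity score in (0, 1): grows with lipophilicity and
    # aromatic load, shrinks with drug-likeness.
    clintox = logistic(-1.5 + 0.3 * logp + 0.25 * arom - 2.0 * props["QED"])
    return {
        "binding_affinity": -2.0 - 0.12 * heavy + 0.2 * abs(logp - 3.0)
        + 0.01 * tpsa,
        "sas": props["SAS"],
        "bioavailability": bioavailability,
        "solubility": solubility,
        "ld50": ld50,
        "clintox": clintox,
    }


#: Orientation of the six drug-design objectives on their natural scales.
SURROGATE_DIRECTIONS = {
    "binding_affinity": "minimize",
    "sas": "minimize",
    "bioavailability": "maximize",
    "solubility": "maximize",
    "ld50": "minimize",
    "clintox": "minimize",
}

_SURROGATE_FAILURES = {
    "binding_affinity": INVALID_DOCKING_VALUE,
    "sas": 10.0,
    "bioavailability": 0.0,
    "solubility": -100.0,
    "ld50": 100.0,
    "clintox": 1.0,
}


# ---------------------------------------------------------------------------
# Docking adapter
# ---------------------------------------------------------------------------

_SCORE_RE = re.compile(r"^\s*1\s+(-?\d+(?:\.\d+)?)", re.MULTILINE)


def docking_adapter(smiles: str, config: DockingConfig,
                    runner: Callable[..., "subprocess.CompletedProcess"] | None = None
                    ) -> float:
    """Best docking score for one ligand via an external Vina-style engine.

    Shells out with the configured box; any failure (non-zero exit,
    unparseable output, bad ligand) yields ``invalid_docking_value``.
    ``runner`` is injectable for testing.
    """
    if config.executable is None:
        raise DockingUnavailableError(
            "no docking executable configured; use the ADMET surrogate for "
            "desk runs or set DockingConfig.executable")
    run = runner or subprocess.run
    try:
        mol = Chem.MolFromSmiles(smiles)
        if mol is None:
            return config.invalid_docking_value
        with tempfile.TemporaryDirectory() as tmp:
            ligand = os.path.join(tmp, "ligand.smi")
            with open(ligand, "w") as fh:
                fh.write(smiles + "\n")
            cmd = [config.executable,
                   "--receptor", str(config.receptor_path),
                   "--ligand", ligand,
                   "--center_x", str(config.center[0]),
                   "--center_y", str(config.center[1]),
                   "--center_z", str(config.center[2]),
                   "--size_x", str(config.size[0]),
                   "--size_y", str(config.size[1]),
                   "--size_z", str(config.size[2])]
            proc = run(cmd, capture_output=True, text=True, timeout=600)
        if proc.returncode != 0:
            return config.invalid_docking_value
        match = _SCORE_RE.search(proc.stdout)
        if match is None:
            return config.invalid_docking_value
        return float(match.group(1))
    except DockingUnavailableError:
        raise
    except Exception:
        return config.invalid_docking_value


# ---------------------------------------------------------------------------
# Registry construction
# ---------------------------------------------------------------------------

def _make_evaluator(kind: str, docking: DockingConfig | None):
    if kind == "sas":
        return lambda smi: compute_properties(smi)["SAS"]
    if kind.startswith("property:"):
        name = kind.split(":", 1)[1]
        return lambda smi: compute_properties(smi)[name]
    if kind.startswith("surrogate_admet:"):
        key = kind.split(":", 1)[1]
        if key not in SURROGATE_DIRECTIONS:
            raise KeyError(f"unknown surrogate endpoint {key!r}")
        return lambda smi: surrogate_admet(smi)[key]
    if kind == "docking":
        config = docking or DockingConfig()
        if config.executable is None or shutil.which(config.executable) is None:
            raise DockingUnavailableError(
                "docking requested but no executable is available; configure "
                "DockingConfig.executable or use 'surrogate_admet:binding_affinity'")
        return lambda smi: docking_adapter(smi, config)
    raise KeyError(f"unknown evaluator kind {kind!r}")


def build_registry(entries: Sequence[dict], docking: DockingConfig | None = None
                   ) -> ObjectiveRegistry:
    """Registry from config entries: ``{name, direction, evaluator[, failure_value]}``.

    Evaluator kinds: ``sas``, ``property:<logP|QED|SAS>``,
    ``surrogate_admet:<endpoint>``, ``docking``.  Missing docking
    executables fail fast here, at build time.
    """
    specs = []
    for entry in entries:
        kind = entry["evaluator"]
        failure = entry.get("failure_value")
        if failure is None:
            if kind == "docking":
                failure = (docking or DockingConfig()).invalid_docking_value
            elif kind.startswith("surrogate_admet:"):
                failure = _SURROGATE_FAILURES[kind.split(":", 1)[1]]
            elif kind in ("sas", "property:SAS"):
                failure = 10.0             # worst point of the 1-10 scale
            elif kind == "property:QED":
                failure = 0.0              # worst drug-likeness
            elif entry["direction"] == "maximize":
                failure = -1e6
            else:
                failure = 1e6
        specs.append(ObjectiveSpec(name=entry["name"],
                                   direction=entry["direction"],
                                   evaluator=_make_evaluator(kind, docking),
                                   failure_value=float(failure)))
    return ObjectiveRegistry(specs)


def default_surrogate_registry() -> ObjectiveRegistry:
    """The full six-objective drug-design panel on the synthetic surrogate."""
    entries = [
        {"name": name, "direction": direction,
         "evaluator": f"surrogate_admet:{name}"}
        for name, direction in SURROGATE_DIRECTIONS.items()
    ]
    entries[1]["evaluator"] = "sas"  # SAS comes straight from the backend
    return build_registry(entries)
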