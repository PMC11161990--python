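"""Latent codec interface: the genotype <-> phenotype map used by optimizers.

Optimizers search a continuous decision space and need two services: encode a
molecule into a fixed-length real vector, and decode any such vector back to
a molecule.  The trained Transformer autoencoders provide one implementation;
:class:`DescriptorCodec` provides a training-free alternative — a library of
molecules embedded at their standardized physicochemical descriptor vectors,
decoded by nearest neighbour — which makes every downstream stage exercisable
deterministically in seconds.
"""

from __future__ import annotations

from typing import Protocol, Sequence, runtime_checkable

import numpy as np
from rdkit import Chem
from rdkit.Chem import Crippen, Descriptors, Lipinski, rdMolDescriptors

from .molecules import canonicalize

__all__ = ["LatentCodec", "DescriptorCodec"]


@runtime_checkable
class LatentCodec(Protocol):
    """Anything that maps molecules to latent vectors and back."""

    @property
    def latent_dim(self) -> int: ...

    def encode_smiles(self, smiles: Sequence[str]) -> np.ndarray:
        """(n, latent_dim) array of latent vectors."""

    def decode_latent(self, z: np.ndarray) -> list[str]:
        """SMILES for each row of ``z`` ('' for the empty molecule)."""


_DESCRIPTOR_FUNCS = (
    lambda m: Crippen.MolLogP(m),
    lambda m: Descriptors.MolWt(m),
    lambda m: rdMolDescriptors.CalcTPSA(m),
    lambda m: m.GetNumHeavyAtoms(),
    lambda m: rdMolDescriptors.CalcNumRings(m),
    lambda m: rdMolDescriptors.CalcNumAromaticRings(m),
    lambda m: Lipinski.NumHDonors(m),
    lambda m: Lipinski.NumHAcceptors(m),
)


def _descriptors(smiles: str) -> np.ndarray:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES: {smiles!r}")
    return np.array([f(mol) for f in _DESCRIPTOR_FUNCS], dtype=float)


class DescriptorCodec:
    """Identity embedding of a molecule library in descriptor space.

    Each library molecule sits at its standardized 8-descriptor vector
    (logP, molecular weight, TPSA, heavy atoms, rings, aromatic rings,
    H-bond donors/acceptors).  ``decode_latent`` snaps an arbitrary vector
    to the nearest library molecule (ties broken by canonical SMILES), so
    decode∘encode is the identity on the library and the repair loop is
    exactly idempotent.
    """

    def __init__(self, library: Sequence[str]) -> None:
        smiles = sorted({canonicalize(s) for s in library})
        if not smiles:
            raise ValueError("library must contain at least one molecule")
        self.library = smiles
        raw = np.stack([_descriptors(s) for s in smiles])
        self._mean = raw.mean(axis=0)
        self._std = raw.std(axis=0)
        self._std[self._std < 1e-9] = 1.0
        self._points = (raw - self._mean) / self._std

    @property
    def latent_dim(self) -> int:
        return self._points.shape[1]

    def encode_smiles(self, smiles: Sequence[str]) -> np.ndarray:
        raw = np.stack([_descriptors(s) for s in smiles])
        return (raw - self._mean) / self._std

    def decode_latent(self, z: np.ndarray) -> list[str]:
        z = np.atleast_2d(np.asarray(z, dtype=float))
        d2 = ((z[:, None, :] - self._points[None, :, :]) ** 2).sum(axis=2)
        # argmin with lexicographic tie-break: library is sorted, and argmin
        # returns the first minimum, which is the lexicographically smallest.
        idx = d2.argmin(axis=1)
        return [self.library[i] for i in idx]
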