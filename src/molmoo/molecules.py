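"""Chemical representation layer.

Converts between SMILES and SELFIES, enumerates alternative SMILES spellings
(the source of contrastive positive pairs), computes the three regularization
properties (logP, QED, SAS), and preprocesses molecule lists into
train/validation/test splits for the autoencoders.

Identity of a molecule is always its RDKit canonical SMILES: deduplication,
caching, uniqueness and novelty all key on it.
"""

from __future__ import annotations

import os
import sys
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem, RDConfig
from rdkit.Chem import Crippen, QED, Descriptors
from rdkit import RDLogger

from . import selfies_codec
from .selfies_codec import CodecError, tokenize

RDLogger.DisableLog("rdApp.*")

sys.path.append(os.path.join(RDConfig.RDContribDir, "SA_Score"))
import sascorer  # noqa: E402  (RDKit contrib implementation of Ertl & Schuffenhauer)

__all__ = [
    "MoleculeRecord",
    "Vocabulary",
    "DatasetSplit",
    "PreprocessingError",
    "canonicalize",
    "smiles_to_selfies",
    "selfies_to_smiles",
    "enumerate_smiles",
    "tokenize",
    "compute_properties",
    "preprocess_dataset",
    "read_smiles_file",
    "read_smiles_csv",
    "write_dataset_csv",
]

PAD, BOS, EOS = "<pad>", "<s>", "</s>"

PROPERTY_NAMES = ("logP", "QED", "SAS")


class PreprocessingError(ValueError):
    """Raised when preprocessing leaves no usable molecules."""


def canonicalize(smiles: str) -> str:
    """Canonical SMILES per the cheminformatics backend; idempotent."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise CodecError(f"unparseable SMILES: {smiles!r}")
    return Chem.MolToSmiles(mol)


def smiles_to_selfies(smiles: str) -> str:
    """Encode a SMILES string as SELFIES (raises CodecError on bad input)."""
    return selfies_codec.encoder(smiles)


def selfies_to_smiles(selfies: str | Sequence[str]) -> str:
    """Decode SELFIES (string or symbol sequence) to a valid SMILES.

    Total over the grammar's alphabet: never fails for known symbols.
    """
    return selfies_codec.decoder(selfies)


def enumerate_smiles(smiles: str, n_attempts: int, rng_seed: int) -> list[str]:
    """Distinct randomized SMILES spellings of one molecule.

    Deterministic per seed: each attempt renumbers the atoms with a seeded
    permutation and writes the molecule non-canonically from that order.
    All variants canonicalize back to the input molecule.
    """
    if n_attempts < 1:
        raise ValueError("n_attempts must be >= 1")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise CodecError(f"unparseable SMILES: {smiles!r}")
    rng = np.random.default_rng(rng_seed)
    n = mol.GetNumAtoms()
    seen: dict[str, None] = {}
    for _ in range(n_attempts):
        order = rng.permutation(n).tolist()
        variant = Chem.MolToSmiles(Chem.RenumberAtoms(mol, order),
                                   canonical=False)
        if Chem.MolFromSmiles(variant) is not None:
            seen.setdefault(variant, None)
    return list(seen)


def compute_properties(smiles: str) -> dict[str, float]:
    """logP (Crippen), QED and SAS (Ertl–Schuffenhauer, scaled 1–10)."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise CodecError(f"unparseable SMILES: {smiles!r}")
    return {
        "logP": float(Crippen.MolLogP(mol)),
        "QED": float(QED.qed(mol)),
        "SAS": float(sascorer.calculateScore(mol)),
    }


@dataclass(frozen=True)
class MoleculeRecord:
    """One molecule with its canonical identity, SELFIES form and properties."""

    smiles_canonical: str
    selfies: str
    tokens: tuple[str, ...]
    properties: dict[str, float] = field(default_factory=dict)

    @classmethod
    def from_smiles(cls, smiles: str, with_properties: bool = True
                    ) -> "MoleculeRecord":
        selfies = smiles_to_selfies(smiles)
        canonical = canonicalize(selfies_to_smiles(selfies))
        props = compute_properties(canonical) if with_properties else {}
        return cls(smiles_canonical=canonical, selfies=selfies,
                   tokens=tuple(tokenize(selfies)), properties=props)

    @property
    def property_vector(self) -> np.ndarray:
        return np.array([self.properties[k] for k in PROPERTY_NAMES])


class Vocabulary:
    """Bijective symbol <-> id map with pad / start / end specials."""

    def __init__(self, symbols: Iterable[str]) -> None:
        ordered = [PAD, BOS, EOS]
        for sym in sorted(set(symbols) - set(ordered)):
            ordered.append(sym)
        self.id_to_symbol: list[str] = ordered
        self.symbol_to_id: dict[str, int] = {s: i for i, s in enumerate(ordered)}

    def __len__(self) -> int:
        return len(self.id_to_symbol)

    @property
    def pad_id(self) -> int:
        return self.symbol_to_id[PAD]

    @property
    def bos_id(self) -> int:
        return self.symbol_to_id[BOS]

    @property
    def eos_id(self) -> int:
        return self.symbol_to_id[EOS]

    def encode(self, tokens: Sequence[str], length: int | None = None
               ) -> np.ndarray:
        """Token ids as ``<s> tokens </s>`` padded to ``length`` if given."""
        try:
            ids = [self.bos_id] + [self.symbol_to_id[t] for t in tokens] \
                + [self.eos_id]
        except KeyError as err:
            raise selfies_codec.VocabularyError(
                f"symbol outside vocabulary: {err.args[0]!r}") from None
        if length is not None:
            if len(ids) > length:
                raise ValueError("sequence longer than requested length")
            ids = ids + [self.pad_id] * (length - len(ids))
        return np.asarray(ids, dtype=np.int64)

    def decode(self, ids: Sequence[int]) -> list[str]:
        """Symbols between start and the first end/pad marker."""
        out = []
        for i in ids:
            sym = self.id_to_symbol[int(i)]
            if sym == BOS:
                continue
            if sym in (EOS, PAD):
                break
            out.append(sym)
        return out

    @classmethod
    def from_records(cls, records: Iterable[MoleculeRecord],
                     include_semantic_alphabet: bool = True) -> "Vocabulary":
        symbols: set[str] = set()
        for rec in records:
            symbols.update(rec.tokens)
        if include_semantic_alphabet:
            symbols.update(selfies_codec.semantic_alphabet())
        return cls(symbols)


@dataclass
class DatasetSplit:
    train: list[MoleculeRecord]
    validation: list[MoleculeRecord]
    test: list[MoleculeRecord]
    fractions: tuple[float, float, float] = (0.70, 0.10, 0.20)

    def all_records(self) -> list[MoleculeRecord]:
        return [*self.train, *self.validation, *self.test]


def preprocess_dataset(smiles_list: Iterable[str], *,
                       max_token_length: int = 198,
                       min_augmentations: int = 2,
                       attempts: int = 10,
                       split_fractions: tuple[float, float, float] = (0.70, 0.10, 0.20),
                       seed: int = 0) -> DatasetSplit:
    """Deduplicate, filter and split a molecule list.

    Filters, in order of the pipeline (they are conjunctive, so order does
    not change the result): drop molecules whose SELFIES tokenization
    exceeds ``max_token_length`` symbols, and drop molecules that do not
    admit at least ``min_augmentations`` unique alternative SMILES
    spellings (the canonical spelling itself excluded) within ``attempts``
    enumeration attempts.  The survivors are split 70/10/20 by a seeded
    shuffle of molecules (never of augmentations, so no molecule leaks
    across splits).
    """
    if abs(sum(split_fractions) - 1.0) > 1e-9:
        raise ValueError("split fractions must sum to 1")
    records: dict[str, MoleculeRecord] = {}
    for smi in smiles_list:
        try:
            rec = MoleculeRecord.from_smiles(smi)
        except CodecError:
            continue
        if rec.smiles_canonical in records:
            continue
        if len(rec.tokens) > max_token_length:
            continue
        variants = enumerate_smiles(rec.smiles_canonical, attempts,
                                    rng_seed=_stable_seed(seed, rec.smiles_canonical))
        unique_aug = [v for v in variants if v != rec.smiles_canonical]
        if len(unique_aug) < min_augmentations:
            continue
        records[rec.smiles_canonical] = rec
    if not records:
        raise PreprocessingError("no molecules survive preprocessing")

    keys = sorted(records)
    rng = np.random.default_rng(seed)
    rng.shuffle(keys)
    n = len(keys)
    n_train = int(round(split_fractions[0] * n))
    n_val = int(round(split_fractions[1] * n))
    train = [records[k] for k in keys[:n_train]]
    val = [records[k] for k in keys[n_train:n_train + n_val]]
    test = [records[k] for k in keys[n_train + n_val:]]
    return DatasetSplit(train=train, validation=val, test=test,
                        fractions=split_fractions)


def _stable_seed(seed: int, text: str) -> int:
    """Seed derived from a base seed and a string, stable across processes."""
    h = 2166136261
    for ch in text:
        h = ((h ^ ord(ch)) * 16777619) & 0xFFFFFFFF
    return (seed * 1000003 + h) % (2 ** 31)


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def read_smiles_file(path: str) -> list[str]:
    """One SMILES per line; blank lines and '#' comments ignored."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                out.append(line.split()[0])
    return out


def read_smiles_csv(path: str, smiles_column: str = "smiles") -> list[str]:
    frame = pd.read_csv(path)
    if smiles_column not in frame.columns:
        raise KeyError(f"column {smiles_column!r} not in {path}")
    return frame[smiles_column].astype(str).tolist()


def write_dataset_csv(split: DatasetSplit, path: str) -> pd.DataFrame:
    rows = []
    for name, records in (("train", split.train), ("validation", split.validation),
                          ("test", split.test)):
        for rec in records:
            rows.append({"smiles": rec.smiles_canonical, "selfies": rec.selfies,
                         "logP": rec.properties.get("logP"),
                         "QED": rec.properties.get("QED"),
                         "SAS": rec.properties.get("SAS"), "split": name})
    frame = pd.DataFrame(rows)
    frame.to_csv(path, index=False)
    return frame
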