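"""SELFIES line notation: a molecular string grammar with a validity guarantee.

SELFIES (SELF-referencing Embedded Strings) represents a molecule as a
sequence of bracketed symbols.  Unlike SMILES, *every* sequence of symbols
over the alphabet decodes to a syntactically and semantically valid
molecule: bond orders are capped by the remaining valence of the atoms
involved, branch and ring lengths are read from explicit index symbols and
clipped to what is actually available.  That totality is what makes the
notation suitable as the output space of a generative model — an argmax
decode of any latent vector is guaranteed to be a molecule.

This module implements the version-2 grammar for neutral organic-subset
molecules (B, C, N, O, P, S and the halogens; no formal charges, isotopes
or stereochemistry).  Encoding mirrors the atom order of the input SMILES
string, so the SELFIES produced for a given SMILES is reproducible and
matches the grammar's reference behaviour; decoding is total over the
alphabet.  RDKit is the chemistry authority throughout: it parses and
kekulizes input on encode and sanitizes the derived graph on decode.
"""

from __future__ import annotations

import re
from typing import Iterable, Sequence

from rdkit import Chem

__all__ = [
    "CodecError",
    "TokenizationError",
    "VocabularyError",
    "tokenize",
    "encoder",
    "decoder",
    "semantic_alphabet",
    "INDEX_ALPHABET",
]


class CodecError(ValueError):
    """Input cannot be represented by this grammar (bad SMILES, charges, ...)."""


class TokenizationError(CodecError):
    """SELFIES text is not a clean sequence of bracketed symbols."""


class VocabularyError(CodecError):
    """A symbol outside the grammar's alphabet was encountered."""


# Maximum bonding capacity per element (neutral, no radicals).
_VALENCES = {
    "B": 3, "C": 4, "N": 3, "O": 2, "P": 5, "S": 6,
    "F": 1, "Cl": 1, "Br": 1, "I": 1,
}

_BOND_PREFIX = {1: "", 2: "=", 3: "#"}
_PREFIX_BOND = {"": 1, "=": 2, "#": 3}

# The 16-symbol overloaded alphabet used to spell out branch lengths and
# ring distances in base 16 (index = position in this tuple).
INDEX_ALPHABET = (
    "[C]", "[Ring1]", "[Ring2]",
    "[Branch1]", "[=Branch1]", "[#Branch1]",
    "[Branch2]", "[=Branch2]", "[#Branch2]",
    "[O]", "[N]", "[=N]", "[=C]", "[#C]", "[S]", "[P]",
)
_INDEX_OF = {s: i for i, s in enumerate(INDEX_ALPHABET)}

_SYMBOL_RE = re.compile(r"\[[^\[\]]*\]")
_ATOM_RE = re.compile(r"\[(=|#)?(B|C|N|O|P|S|F|Cl|Br|I)\]")
_BRANCH_RE = re.compile(r"\[(=|#)?Branch([123])\]")
_RING_RE = re.compile(r"\[(=|#)?Ring([123])\]")


def tokenize(selfies: str) -> list[str]:
    """Split a SELFIES string into its bracketed symbols.

    Raises :class:`TokenizationError` if any text falls outside brackets.
    """
    symbols = _SYMBOL_RE.findall(selfies)
    if "".join(symbols) != selfies:
        raise TokenizationError(
            f"text outside bracketed symbols in SELFIES string: {selfies!r}"
        )
    return symbols


def semantic_alphabet() -> list[str]:
    """All symbols the decoder understands (excludes model-side specials)."""
    out = ["[nop]"]
    for elem in _VALENCES:
        for order, prefix in _BOND_PREFIX.items():
            if order <= _VALENCES[elem]:
                out.append(f"[{prefix}{elem}]")
    for kind in ("Branch", "Ring"):
        for level in (1, 2, 3):
            for prefix in ("", "=", "#"):
                out.append(f"[{prefix}{kind}{level}]")
    return out


def _classify(symbol: str):
    """Return ('atom', element, order) | ('branch', level, order) |
    ('ring', level, order) | ('nop',)."""
    if symbol == "[nop]":
        return ("nop",)
    m = _ATOM_RE.fullmatch(symbol)
    if m:
        return ("atom", m.group(2), _PREFIX_BOND[m.group(1) or ""])
    m = _BRANCH_RE.fullmatch(symbol)
    if m:
        return ("branch", int(m.group(2)), _PREFIX_BOND[m.group(1) or ""])
    m = _RING_RE.fullmatch(symbol)
    if m:
        return ("ring", int(m.group(2)), _PREFIX_BOND[m.group(1) or ""])
    raise VocabularyError(f"unknown SELFIES symbol: {symbol!r}")


def _index_symbols(value: int) -> list[str]:
    """Spell a nonnegative integer in base 16 using the index alphabet."""
    if value < 16:
        digits = [value]
    elif value < 16 ** 2:
        digits = [value // 16, value % 16]
    else:
        digits = [(value // 256) % 16, (value // 16) % 16, value % 16]
    return [INDEX_ALPHABET[d] for d in digits]


def _read_index(symbols: Sequence[str], start: int, length: int) -> int:
    value = 0
    for k in range(length):
        digit = 0
        if start + k < len(symbols):
            digit = _INDEX_OF.get(symbols[start + k], 0)
        value = value * 16 + digit
    return value


# ---------------------------------------------------------------------------
# Encoding: SMILES -> SELFIES
# ---------------------------------------------------------------------------

def _prepare_mol(smiles: str) -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise CodecError(f"unparseable SMILES: {smiles!r}")
    Chem.RemoveStereochemistry(mol)
    for atom in mol.GetAtoms():
        if atom.GetSymbol() not in _VALENCES:
            raise CodecError(
                f"element {atom.GetSymbol()!r} outside the supported organic subset"
            )
        if atom.GetFormalCharge() != 0:
            raise CodecError("formal charges are not supported by this grammar")
        if atom.GetIsotope() != 0:
            raise CodecError("isotopes are not supported by this grammar")
        if atom.GetNumRadicalElectrons() != 0:
            raise CodecError("radicals are not supported by this grammar")
    Chem.Kekulize(mol, clearAromaticFlags=True)
    return mol


def encoder(smiles: str) -> str:
    """Encode a SMILES string as SELFIES, mirroring its atom order.

    The traversal follows the order in which atoms and bonds appear in the
    input string (RDKit preserves both), so a given SMILES always maps to
    the same SELFIES and ring/branch indices match the grammar's reference
    layout.
    """
    mol = _prepare_mol(smiles)
    if mol.GetNumAtoms() == 0:
        return ""

    visited: dict[int, int] = {}          # atom idx -> emission position
    used_bonds: set[int] = set()

    def neighbors_in_bond_order(idx: int):
        pairs = []
        for bond in mol.GetAtomWithIdx(idx).GetBonds():
            other = bond.GetOtherAtomIdx(idx)
            pairs.append((bond.GetIdx(), other, bond))
        pairs.sort(key=lambda t: t[0])
        return pairs

    def emit(idx: int, bond_order: int) -> list[str]:
        """Emit the symbol for atom ``idx`` entered via ``bond_order`` and
        everything hanging off it (rings, branches, chain continuation)."""
        visited[idx] = len(visited)
        elem = mol.GetAtomWithIdx(idx).GetSymbol()
        out = [f"[{_BOND_PREFIX[bond_order]}{elem}]"]

        # Bonds are examined lazily, in the order they appear in the input
        # string: a neighbour that is unvisited *now* may become a ring
        # closure once an earlier sibling's subtree has been walked, and a
        # child is a parenthesised branch only if bonds remain afterwards.
        while True:
            pending = [t for t in neighbors_in_bond_order(idx)
                       if t[0] not in used_bonds]
            if not pending:
                break
            bond_idx, other, bond = pending[0]
            used_bonds.add(bond_idx)
            order = int(bond.GetBondTypeAsDouble())
            if other in visited:
                distance = visited[idx] - visited[other] - 1
                idx_syms = _index_symbols(distance)
                out.append(f"[{_BOND_PREFIX[order]}Ring{len(idx_syms)}]")
                out.extend(idx_syms)
                continue
            sub = emit(other, order)
            still_open = any(t[0] not in used_bonds
                             for t in neighbors_in_bond_order(idx))
            if still_open:
                idx_syms = _index_symbols(len(sub) - 1)
                out.append(f"[{_BOND_PREFIX[order]}Branch{len(idx_syms)}]")
                out.extend(idx_syms)
            out.extend(sub)
        return out

    return "".join(emit(0, 1))


# ---------------------------------------------------------------------------
# Decoding: SELFIES -> SMILES (total over the alphabet)
# ---------------------------------------------------------------------------

class _Graph:
    def __init__(self) -> None:
        self.elements: list[str] = []
        self.caps: list[int] = []
        self.bonds: dict[tuple[int, int], int] = {}

    def add_atom(self, elem: str) -> int:
        self.elements.append(elem)
        self.caps.append(_VALENCES[elem])
        return len(self.elements) - 1

    def add_bond(self, a: int, b: int, order: int) -> None:
        key = (min(a, b), max(a, b))
        self.bonds[key] = order
        self.caps[a] -= order
        self.caps[b] -= order


def _derive(graph: _Graph, symbols: Sequence[str], attach: int | None,
            state: int) -> None:
    """Derive atoms from ``symbols`` attached to atom ``attach`` which has
    ``state`` free valences left for this scope.  Mutates ``graph``."""
    i = 0
    n = len(symbols)
    while i < n:
        kind = _classify(symbols[i])
        i += 1
        if kind[0] == "nop":
            continue

        if kind[0] == "atom":
            _, elem, order = kind
            if attach is None:
                new = graph.add_atom(elem)
                attach, state = new, graph.caps[new]
                continue
            if state <= 0:
                return  # previous atom saturated: rest of scope is dropped
            bond = min(order, state, _VALENCES[elem])
            new = graph.add_atom(elem)
            graph.add_bond(attach, new, bond)
            attach, state = new, graph.caps[new]
            continue

        if kind[0] == "branch":
            _, level, order = kind
            if attach is None or state <= 1:
                continue  # acts as a no-op in states X0/X1
            length = _read_index(symbols, i, level) + 1
            i += level
            body = symbols[i:i + length]
            i += length
            _derive(graph, body, attach, min(order, state - 1))
            state = graph.caps[attach]
            continue

        if kind[0] == "ring":
            _, level, order = kind
            distance = _read_index(symbols, i, level)
            i += level
            if attach is None or state < 1:
                continue
            # Distances count back from the current attachment atom in
            # derivation order (branch atoms derived in between do not shift
            # the reference point).
            target = attach - (distance + 1)
            if target < 0:
                target = 0
            if target == attach:
                continue
            key = (min(attach, target), max(attach, target))
            if key in graph.bonds:
                continue
            bond = min(order, state, graph.caps[target])
            if bond < 1:
                continue
            graph.add_bond(attach, target, bond)
            state = graph.caps[attach]
            continue


_BOND_TYPE = {1: Chem.BondType.SINGLE, 2: Chem.BondType.DOUBLE,
              3: Chem.BondType.TRIPLE}


def decoder(selfies: str | Iterable[str]) -> str:
    """Decode a SELFIES string (or symbol sequence) into a canonical SMILES.

    Total over the alphabet: any sequence of known symbols yields a valid
    (possibly empty) molecule.  Unknown symbols raise
    :class:`VocabularyError`.
    """
    if isinstance(selfies, str):
        symbols = tokenize(selfies)
    else:
        symbols = list(selfies)
    for sym in symbols:
        _classify(sym)  # fail fast on unknown symbols

    graph = _Graph()
    _derive(graph, symbols, None, 0)
    if not graph.elements:
        return ""

    rw = Chem.RWMol()
    for elem in graph.elements:
        rw.AddAtom(Chem.Atom(elem))
    for (a, b), order in graph.bonds.items():
        rw.AddBond(a, b, _BOND_TYPE[order])
    mol = rw.GetMol()
    Chem.SanitizeMol(mol)
    return Chem.MolToSmiles(mol)
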