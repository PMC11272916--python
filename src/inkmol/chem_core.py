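"""SMILES handling for the C/H/O, at-most-one-ring chemical scope.

This module owns the chemical side of the pipeline: parsing SMILES into a
light molecular-graph container, canonicalization (delegated to RDKit's
canonical atom ranking), randomized SMILES writing, a character-level
tokenizer over the generation alphabet, the scope filter that defines which
molecules the pipeline covers, and an exhaustive enumerator of small C/H/O
molecules used as a self-contained corpus source.

Molecules here contain only carbon, hydrogen and oxygen and at most one
ring; hydrogens are always implicit in written SMILES (the generation
alphabet has no ``H``).
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np
from rdkit import Chem, RDLogger
from rdkit.Chem import rdmolops

RDLogger.DisableLog("rdApp.*")

ALLOWED_ELEMENTS = frozenset({"C", "H", "O"})

#: maximum total bond valence per element within scope
MAX_VALENCE = {"C": 4, "O": 2, "H": 1}


class SmilesError(ValueError):
    """Base class for SMILES handling failures."""


class SmilesParseError(SmilesError):
    """The string is not syntactically valid SMILES.

    ``position`` is the 0-based index of the offending character when it
    can be determined (e.g. an unbalanced parenthesis), else ``None``.
    """

    def __init__(self, text: str, position: int | None = None, reason: str = ""):
        self.text = text
        self.position = position
        msg = f"cannot parse SMILES {text!r}"
        if position is not None:
            msg += f" (at position {position})"
        if reason:
            msg += f": {reason}"
        super().__init__(msg)


class ChemistryError(SmilesError):
    """Syntactically valid SMILES describing a chemically invalid molecule
    (typically a valence violation)."""


@dataclass(frozen=True)
class MoleculeGraph:
    """Heavy-atom graph of a molecule.

    atoms: ``(element symbol, aromatic flag)`` per heavy atom.
    bonds: ``(i, j, order)`` with order in ``{1, 2, 3}`` or the string
        ``"ar"`` for aromatic bonds.
    ring_count: smallest-set-of-smallest-rings count of the heavy-atom graph.
    """

    atoms: tuple[tuple[str, bool], ...]
    bonds: tuple[tuple[int, int, object], ...]
    ring_count: int
    _rdmol: Chem.Mol | None = field(default=None, compare=False, repr=False)

    @property
    def n_heavy_atoms(self) -> int:
        return len(self.atoms)

    def elements(self) -> set[str]:
        return {sym for sym, _ in self.atoms}

    def to_rdkit(self) -> Chem.Mol:
        """Return the underlying RDKit molecule (sanitized)."""
        if self._rdmol is not None:
            return self._rdmol
        rw = Chem.RWMol()
        for sym, arom in self.atoms:
            a = Chem.Atom(sym)
            a.SetIsAromatic(arom)
            rw.AddAtom(a)
        order_map = {1: Chem.BondType.SINGLE, 2: Chem.BondType.DOUBLE,
                     3: Chem.BondType.TRIPLE, "ar": Chem.BondType.AROMATIC}
        for i, j, order in self.bonds:
            rw.AddBond(int(i), int(j), order_map[order])
        mol = rw.GetMol()
        Chem.SanitizeMol(mol)
        return mol


def _find_unbalanced(text: str) -> int | None:
    """Position of the first unbalanced parenthesis, if any."""
    depth = 0
    for pos, ch in enumerate(text):
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
            if depth < 0:
                return pos
    if depth > 0:
        return text.rindex("(")
    return None


def _graph_from_rdkit(mol: Chem.Mol) -> MoleculeGraph:
    atoms = tuple((a.GetSymbol(), a.GetIsAromatic()) for a in mol.GetAtoms())
    bonds = []
    for b in mol.GetBonds():
        if b.GetBondType() == Chem.BondType.AROMATIC:
            order: object = "ar"
        else:
            order = int(b.GetBondTypeAsDouble())
        bonds.append((b.GetBeginAtomIdx(), b.GetEndAtomIdx(), order))
    ring_count = len(rdmolops.GetSSSR(mol))
    return MoleculeGraph(atoms=atoms, bonds=tuple(bonds),
                         ring_count=int(ring_count), _rdmol=mol)


def parse_smiles(text: str) -> MoleculeGraph:
    """Parse a SMILES string into a :class:`MoleculeGraph`.

    Raises :class:`SmilesParseError` on syntax errors (with the position of
    the first unbalanced parenthesis when that is the cause) and
    :class:`ChemistryError` when the string is syntactically valid but
    chemically impossible (valence violations).
    """
    if not text:
        raise SmilesParseError(text, reason="empty string")
    mol = Chem.MolFromSmiles(text, sanitize=False)
    if mol is None:
        raise SmilesParseError(text, position=_find_unbalanced(text))
    try:
        Chem.SanitizeMol(mol)
    except Exception as exc:  # RDKit raises several sanitization subclasses
        raise ChemistryError(f"invalid chemistry in {text!r}: {exc}") from exc
    return _graph_from_rdkit(mol)


def canonicalize(text: str) -> str:
    """Return the canonical SMILES for ``text``.

    The output is invariant under atom reordering of the input and is a
    fixed point of this function. Delegates atom ranking to RDKit.
    """
    graph = parse_smiles(text)
    return Chem.MolToSmiles(graph.to_rdkit())


def randomized_smiles(m: MoleculeGraph | str, seed: int) -> str:
    """Write ``m`` as SMILES starting from a seeded random atom ordering.

    Different seeds may give different strings; all of them canonicalize to
    the same form. Deterministic per seed.
    """
    if isinstance(m, str):
        m = parse_smiles(m)
    mol = m.to_rdkit()
    rng = np.random.default_rng(seed)
    perm = [int(x) for x in rng.permutation(mol.GetNumAtoms())]
    shuffled = Chem.RenumberAtoms(mol, perm)
    return Chem.MolToSmiles(shuffled, canonical=False)


# ---------------------------------------------------------------------------
# Vocabulary and tokenization


PAD, BOS, EOS = "<pad>", "<bos>", "<eos>"

#: the generation alphabet: bonds, branches, one ring-closure digit, atoms
DEFAULT_ALPHABET = ("#", "(", ")", "1", "=", "C", "O", "c", "o")


class TokenizationError(SmilesError):
    """A character of the input is outside the vocabulary."""


@dataclass(frozen=True)
class Vocabulary:
    """Character vocabulary with reserved padding/start/end symbols.

    ``tokens`` always begins with PAD, BOS, EOS followed by the chemistry
    alphabet; ``max_len`` caps the unframed SMILES length.
    """

    tokens: tuple[str, ...] = (PAD, BOS, EOS) + DEFAULT_ALPHABET
    max_len: int = 30

    def __post_init__(self):
        if len(set(self.tokens)) != len(self.tokens):
            raise ValueError("vocabulary tokens must be unique")
        for reserved in (PAD, BOS, EOS):
            if reserved not in self.tokens:
                raise ValueError(f"missing reserved token {reserved!r}")

    @property
    def pad_id(self) -> int:
        return self.tokens.index(PAD)

    @property
    def bos_id(self) -> int:
        return self.tokens.index(BOS)

    @property
    def eos_id(self) -> int:
        return self.tokens.index(EOS)

    def __len__(self) -> int:
        return len(self.tokens)

    def index(self, token: str) -> int:
        try:
            return self.tokens.index(token)
        except ValueError:
            raise TokenizationError(f"out-of-vocabulary character {token!r}") from None

    def to_json(self) -> str:
        return json.dumps({"tokens": list(self.tokens), "max_len": self.max_len})

    @classmethod
    def from_json(cls, payload: str) -> "Vocabulary":
        data = json.loads(payload)
        return cls(tokens=tuple(data["tokens"]), max_len=int(data["max_len"]))


def tokenize(text: str, vocab: Vocabulary | None = None) -> list[int]:
    """Character-level tokenization with BOS/EOS framing.

    Raises :class:`TokenizationError` naming the first character outside the
    vocabulary. The C/H/O alphabet has no multi-character element symbols,
    so one character is one token.
    """
    vocab = vocab or Vocabulary()
    ids = [vocab.bos_id]
    for ch in text:
        ids.append(vocab.index(ch))
    ids.append(vocab.eos_id)
    return ids


def detokenize(ids: Sequence[int], vocab: Vocabulary | None = None) -> str:
    """Inverse of :func:`tokenize`; strips framing and padding."""
    vocab = vocab or Vocabulary()
    special = {vocab.pad_id, vocab.bos_id, vocab.eos_id}
    out = []
    for i in ids:
        if int(i) == vocab.eos_id:
            break
        if int(i) in special:
            continue
        out.append(vocab.tokens[int(i)])
    return "".join(out)


# ---------------------------------------------------------------------------
# Scope filter


def passes_scope_filter(text: str, max_rings: int = 1, max_len: int = 30) -> bool:
    """True iff ``text`` is valid SMILES within the pipeline's chemical scope:
    elements within C/H/O, at most ``max_rings`` rings and at most
    ``max_len`` characters. Unparseable strings are simply out of scope."""
    if len(text) > max_len:
        return False
    try:
        graph = parse_smiles(text)
    except SmilesError:
        return False
    if not graph.elements() <= ALLOWED_ELEMENTS:
        return False
    return graph.ring_count <= max_rings


# ---------------------------------------------------------------------------
# Exhaustive C/H/O enumerator


def _tree_skeletons(n: int) -> Iterator[tuple[tuple[int, int], ...]]:
    """Non-isomorphic free trees on ``n`` nodes, as edge tuples."""
    if n == 1:
        yield ()
        return
    import networkx as nx

    for t in nx.nonisomorphic_trees(n):
        yield tuple((int(u), int(v)) for u, v in t.edges())


def _skeletons(n: int, max_rings: int) -> Iterator[tuple[tuple[int, int], ...]]:
    """Connected heavy-atom skeletons on ``n`` nodes with at most
    ``max_rings`` independent cycles. Duplicate isomorphs may be yielded;
    canonical-SMILES dedup removes them downstream."""
    for tree in _tree_skeletons(n):
        yield tree
        if max_rings >= 1 and n >= 3:
            present = set(tree) | {(v, u) for u, v in tree}
            for u, v in itertools.combinations(range(n), 2):
                if (u, v) not in present:
                    yield tree + ((u, v),)


def _assign_orders(edges, elements, idx, orders, used):
    """DFS over bond orders with valence pruning; yields full assignments."""
    if idx == len(edges):
        yield tuple(orders)
        return
    u, v = edges[idx]
    cap_u = MAX_VALENCE[elements[u]] - used[u]
    cap_v = MAX_VALENCE[elements[v]] - used[v]
    for order in (1, 2, 3):
        if order <= cap_u and order <= cap_v:
            used[u] += order
            used[v] += order
            orders.append(order)
            yield from _assign_orders(edges, elements, idx + 1, orders, used)
            orders.pop()
            used[u] -= order
            used[v] -= order


def enumerate_cho(max_heavy_atoms: int, max_rings: int = 1) -> list[str]:
    """Exhaustively enumerate canonical SMILES of connected C/O heavy-atom
    molecules (hydrogens implicit) with up to ``max_heavy_atoms`` heavy atoms
    and at most ``max_rings`` rings.

    The list is duplicate-free by canonical form and sorted by
    ``(length, text)`` so the order is deterministic. Guarded at 8 heavy
    atoms to keep the combinatorics desk-sized.
    """
    if max_heavy_atoms < 1:
        raise ValueError("max_heavy_atoms must be >= 1")
    if max_heavy_atoms > 8:
        raise ValueError("max_heavy_atoms > 8 exceeds the enumeration guard")
    if max_rings < 0:
        raise ValueError("max_rings must be >= 0")

    seen: set[str] = set()
    for n in range(1, max_heavy_atoms + 1):
        for edges in _skeletons(n, max_rings):
            for elem_tuple in itertools.product("CO", repeat=n):
                used = [0] * n
                ok = True
                # quick degree bound before order assignment
                deg = [0] * n
                for u, v in edges:
                    deg[u] += 1
                    deg[v] += 1
                for a in range(n):
                    if deg[a] > MAX_VALENCE[elem_tuple[a]]:
                        ok = False
                        break
                if not ok:
                    continue
                for orders in _assign_orders(list(edges), elem_tuple, 0, [], used):
                    rw = Chem.RWMol()
                    for sym in elem_tuple:
                        rw.AddAtom(Chem.Atom(sym))
                    btype = {1: Chem.BondType.SINGLE, 2: Chem.BondType.DOUBLE,
                             3: Chem.BondType.TRIPLE}
                    for (u, v), order in zip(edges, orders):
                        rw.AddBond(u, v, btype[order])
                    mol = rw.GetMol()
                    try:
                        Chem.SanitizeMol(mol)
                    except Exception:
                        continue
                    if len(rdmolops.GetSSSR(mol)) > max_rings:
                        continue
                    seen.add(Chem.MolToSmiles(mol))
    return sorted(seen, key=lambda s: (len(s), s))


def read_smiles_file(path) -> list[str]:
    """Read a SMILES corpus: one SMILES per line, UTF-8, ``#`` lines and
    blank lines skipped."""
    out = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            out.append(line)
    return out


def write_smiles_file(path, smiles: Sequence[str]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for s in smiles:
            fh.write(s + "\n")
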