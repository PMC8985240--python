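"""Molecular graphs parsed from SMILES.

The module provides the substrate for everything downstream: a small,
explicit molecular-graph model (heavy atoms only, hydrogens implicit)
with a valence model, ring perception and kekulization of aromatic
systems.  The supported SMILES dialect is the organic subset plus
bracket atoms with formal charges and explicit hydrogen counts, ring
closures, branches and double/triple/aromatic bonds — enough to express
small hydrophilic monomers (amides, esters, hydroxyls, sulfonates,
phosphates, quaternary ammonium, aromatic azinium rings, zwitterions).
Stereochemistry and isotopes are deliberately out of dialect.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import networkx as nx

__all__ = [
    "Atom",
    "Bond",
    "Molecule",
    "SmilesParseError",
    "parse_smiles",
    "write_smiles",
    "ring_perception",
    "implicit_hydrogen_count",
    "read_smi",
]

# Default valences; multivalent elements list the allowed states in
# increasing order (smallest state >= bond-order sum is filled with H).
_VALENCES = {
    "C": (4,),
    "N": (3,),
    "O": (2,),
    "S": (2, 4, 6),
    "P": (3, 5),
    "F": (1,),
    "Cl": (1,),
    "Br": (1,),
}

_ORGANIC_SUBSET = ("Cl", "Br", "C", "N", "O", "S", "P", "F")
_AROMATIC_SYMBOLS = ("c", "n", "o", "s")

_BOND_CHARS = {"-": 1, "=": 2, "#": 3, ":": "ar"}
_ORDER_NAMES = {1: "single", 2: "double", 3: "triple", "ar": "aromatic"}


class SmilesParseError(ValueError):
    """Raised for malformed SMILES; carries the offending position."""

    def __init__(self, message: str, position: int | None = None):
        self.position = position
        if position is not None:
            message = f"{message} (at position {position})"
        super().__init__(message)


@dataclass
class Atom:
    index: int
    element: str
    formal_charge: int = 0
    aromatic: bool = False
    implicit_h: int = 0
    in_ring: bool = False
    # explicit H count from a bracket token; None => fill by valence model
    _explicit_h: int | None = field(default=None, repr=False, compare=False)


@dataclass
class Bond:
    i: int
    j: int
    order: str  # "single" | "double" | "triple" | "aromatic"
    in_ring: bool = False
    kek_order: int = 0  # kekulized integer order (aromatic -> 1 or 2)

    @property
    def endpoints(self) -> tuple[int, int]:
        return (self.i, self.j)


class Molecule:
    """Labelled undirected molecular graph (heavy atoms + implicit H)."""

    def __init__(self, identifier: str, atoms: list[Atom], bonds: list[Bond],
                 source_smiles: str = ""):
        self.identifier = identifier
        self.atoms = atoms
        self.bonds = bonds
        self.source_smiles = source_smiles
        self._adj: dict[int, dict[int, Bond]] = {a.index: {} for a in atoms}
        for b in bonds:
            if b.i == b.j:
                raise ValueError("self-bond")
            if b.j in self._adj[b.i]:
                raise ValueError(f"duplicate bond {b.i}-{b.j}")
            self._adj[b.i][b.j] = b
            self._adj[b.j][b.i] = b

    # -- basic accessors -------------------------------------------------
    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def heavy_atom_count(self) -> int:
        return len(self.atoms)

    def neighbors(self, i: int) -> list[int]:
        return sorted(self._adj[i])

    def bond_between(self, i: int, j: int) -> Bond | None:
        return self._adj[i].get(j)

    def degree(self, i: int) -> int:
        return len(self._adj[i])

    def bond_order_sum(self, i: int) -> int:
        """Sum of kekulized bond orders at atom i."""
        return sum(b.kek_order for b in self._adj[i].values())

    @property
    def net_charge(self) -> int:
        return sum(a.formal_charge for a in self.atoms)

    def total_h(self) -> int:
        return sum(a.implicit_h for a in self.atoms)

    def formula(self) -> str:
        """Hill-order molecular formula including implicit hydrogens."""
        counts: dict[str, int] = {}
        for a in self.atoms:
            counts[a.element] = counts.get(a.element, 0) + 1
        h = self.total_h()
        parts = []
        for el in ["C", "H"] + sorted(e for e in counts if e not in ("C", "H")):
            n = counts.get(el, 0) if el != "H" else h
            if n:
                parts.append(el + (str(n) if n > 1 else ""))
        return "".join(parts)

    def is_connected(self) -> bool:
        if not self.atoms:
            return False
        return nx.is_connected(self.to_networkx())

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        for a in self.atoms:
            g.add_node(a.index, element=a.element, charge=a.formal_charge,
                       aromatic=a.aromatic)
        for b in self.bonds:
            g.add_edge(b.i, b.j, order=b.order, kek_order=b.kek_order)
        return g

    def to_json(self) -> str:
        return json.dumps({
            "identifier": self.identifier,
            "source_smiles": self.source_smiles,
            "atoms": [{"index": a.index, "element": a.element,
                       "charge": a.formal_charge, "aromatic": a.aromatic,
                       "implicit_h": a.implicit_h, "in_ring": a.in_ring}
                      for a in self.atoms],
            "bonds": [{"i": b.i, "j": b.j, "order": b.order,
                       "kek_order": b.kek_order, "in_ring": b.in_ring}
                      for b in self.bonds],
        }, indent=1)


# ---------------------------------------------------------------------------
# valence model
# ---------------------------------------------------------------------------

def _allowed_valences(element: str, charge: int) -> tuple[int, ...]:
    base = _VALENCES[element]
    if charge == 0:
        return base
    if element in ("N", "P") and charge > 0:
        return tuple(v + charge for v in base)
    # anionic O/S/C and the like lose one bonding slot per unit charge
    return tuple(max(0, v - abs(charge)) for v in base)


def implicit_hydrogen_count(element: str, charge: int, bond_order_sum: int) -> int:
    """Hydrogens needed to fill the smallest allowed valence state.

    Standard-valence fill (C4, N3, O2, S2/4/6, P3/5), with N/P cations
    gaining a bonding slot per positive charge and O/S/C anions losing
    one per negative charge (so sulfonate/carboxylate O- carry no H and
    quaternary N+ carries none).
    """
    if element not in _VALENCES:
        raise ValueError(f"unsupported element {element!r}")
    for v in _allowed_valences(element, charge):
        if bond_order_sum <= v:
            return v - bond_order_sum
    raise ValueError(
        f"valence overflow: {element} (charge {charge:+d}) with bond order "
        f"sum {bond_order_sum}")


# ---------------------------------------------------------------------------
# SMILES tokenizer / parser
# ---------------------------------------------------------------------------

def _read_bracket(s: str, start: int) -> tuple[Atom, int]:
    """Parse a bracket atom starting at s[start] == '['; returns (atom, end)."""
    i = start + 1
    n = len(s)
    if i < n and s[i].isdigit():
        raise SmilesParseError("isotopes not supported", i)
    # element symbol
    sym = None
    for cand in ("Cl", "Br"):
        if s.startswith(cand, i):
            sym = cand
            break
    if sym is None and i < n and (s[i].isalpha()):
        sym = s[i]
    if sym is None:
        raise SmilesParseError("expected element symbol in bracket", i)
    i += len(sym)
    aromatic = sym.islower()
    element = sym.upper() if aromatic else sym
    if aromatic and sym not in _AROMATIC_SYMBOLS:
        raise SmilesParseError(f"unsupported aromatic symbol {sym!r}", start)
    if element not in _VALENCES:
        raise SmilesParseError(f"unknown element {sym!r}", start)
    if i < n and s[i] == "@":
        raise SmilesParseError("stereochemistry not supported", i)
    hcount = 0
    if i < n and s[i] == "H":
        i += 1
        hcount = 1
        if i < n and s[i].isdigit():
            hcount = int(s[i])
            i += 1
    charge = 0
    if i < n and s[i] in "+-":
        sign = 1 if s[i] == "+" else -1
        i += 1
        if i < n and s[i].isdigit():
            charge = sign * int(s[i])
            i += 1
        else:
            charge = sign
            while i < n and s[i] in "+-":  # e.g. "--"
                if (s[i] == "+") != (sign == 1):
                    raise SmilesParseError("mixed charge signs", i)
                charge += sign
                i += 1
    if i >= n or s[i] != "]":
        raise SmilesParseError("unclosed bracket atom", start)
    atom = Atom(index=-1, element=element, formal_charge=charge,
                aromatic=aromatic, _explicit_h=hcount)
    return atom, i + 1


def _tokenize_atoms(smiles: str, identifier: str) -> Molecule:
    atoms: list[Atom] = []
    bonds: list[Bond] = []
    bond_keys: set[tuple[int, int]] = set()
    stack: list[int] = []
    prev: int | None = None
    pending_bond: int | str | None = None
    ring_open: dict[int, tuple[int, int | str | None, int]] = {}

    def add_bond(i: int, j: int, order: int | str | None, pos: int) -> None:
        if order is None:
            order = "ar" if (atoms[i].aromatic and atoms[j].aromatic) else 1
        key = (min(i, j), max(i, j))
        if i == j:
            raise SmilesParseError("ring closure to the same atom", pos)
        if key in bond_keys:
            raise SmilesParseError(f"duplicate bond {i}-{j}", pos)
        bond_keys.add(key)
        bonds.append(Bond(i=i, j=j, order=_ORDER_NAMES[order],
                          kek_order=0 if order == "ar" else order))

    i = 0
    n = len(smiles)
    while i < n:
        ch = smiles[i]
        if ch.isspace():
            raise SmilesParseError("whitespace inside SMILES", i)
        if ch == "(":
            if prev is None:
                raise SmilesParseError("branch before any atom", i)
            stack.append(prev)
            i += 1
            continue
        if ch == ")":
            if not stack:
                raise SmilesParseError("unbalanced parenthesis", i)
            prev = stack.pop()
            i += 1
            continue
        if ch in _BOND_CHARS:
            if pending_bond is not None:
                raise SmilesParseError("two bond symbols in a row", i)
            pending_bond = _BOND_CHARS[ch]
            i += 1
            continue
        if ch == ".":
            raise SmilesParseError("disconnected fragments not supported", i)
        if ch.isdigit() or ch == "%":
            if prev is None:
                raise SmilesParseError("ring closure before any atom", i)
            if ch == "%":
                if i + 2 >= n or not smiles[i + 1:i + 3].isdigit():
                    raise SmilesParseError("malformed %nn ring closure", i)
                num = int(smiles[i + 1:i + 3])
                i += 3
            else:
                num = int(ch)
                i += 1
            if num in ring_open:
                j, order0, _ = ring_open.pop(num)
                order = pending_bond if pending_bond is not None else order0
                add_bond(prev, j, order, i - 1)
            else:
                ring_open[num] = (prev, pending_bond, i - 1)
            pending_bond = None
            continue
        # atom token
        if ch == "[":
            atom, i = _read_bracket(smiles, i)
        else:
            sym = None
            for cand in _ORGANIC_SUBSET:
                if smiles.startswith(cand, i):
                    sym = cand
                    break
            if sym is None and ch in _AROMATIC_SYMBOLS:
                sym = ch
            if sym is None:
                raise SmilesParseError(f"unknown token {ch!r}", i)
            aromatic = sym.islower()
            atom = Atom(index=-1, element=sym.upper() if aromatic else sym,
                        aromatic=aromatic)
            i += len(sym)
        atom.index = len(atoms)
        atoms.append(atom)
        if prev is not None:
            if pending_bond == "ar" and not (atoms[prev].aromatic and atom.aromatic):
                raise SmilesParseError("aromatic bond between non-aromatic atoms", i)
            add_bond(prev, atom.index, pending_bond, i - 1)
        elif pending_bond is not None:
            raise SmilesParseError("bond symbol before first atom", i)
        pending_bond = None
        prev = atom.index

    if stack:
        raise SmilesParseError("unbalanced parenthesis", n)
    if ring_open:
        num, (_, _, pos) = sorted(ring_open.items())[0]
        raise SmilesParseError(f"unmatched ring-closure digit {num}", pos)
    if pending_bond is not None:
        raise SmilesParseError("dangling bond symbol", n)
    if not atoms:
        raise SmilesParseError("empty SMILES", 0)
    return Molecule(identifier, atoms, bonds, source_smiles=smiles)


# ---------------------------------------------------------------------------
# kekulization and hydrogen assignment
# ---------------------------------------------------------------------------

def _needs_double(mol: Molecule, a: Atom) -> bool:
    """Does this aromatic atom contribute one double bond to the kekule
    structure?  Carbon always does; pyridine-type (2-connected neutral n or
    3-connected n+) nitrogen does; pyrrole-type nitrogen ([nH] or
    3-connected neutral n) and aromatic o/s do not."""
    if a.element == "C":
        return True
    if a.element == "N":
        deg = mol.degree(a.index)
        h = a._explicit_h or 0
        if a.formal_charge > 0:
            return deg + h >= 3
        return deg == 2 and h == 0
    return False  # O, S


def _kekulize(mol: Molecule) -> None:
    arom_bonds = [b for b in mol.bonds if b.order == "aromatic"]
    if not arom_bonds:
        for a in mol.atoms:
            if a.aromatic:
                raise SmilesParseError(
                    f"aromatic atom {a.index} has no aromatic bonds")
        return
    need = {a.index for a in mol.atoms if a.aromatic and _needs_double(mol, a)}
    adj: dict[int, list[int]] = {}
    for b in arom_bonds:
        if b.i in need and b.j in need:
            adj.setdefault(b.i, []).append(b.j)
            adj.setdefault(b.j, []).append(b.i)
    for k in adj:
        adj[k].sort()
    order = sorted(need)
    match: dict[int, int] = {}

    def backtrack(idx: int) -> bool:
        if idx == len(order):
            return True
        u = order[idx]
        if u in match:
            return backtrack(idx + 1)
        for v in adj.get(u, []):
            if v not in match:
                match[u] = v
                match[v] = u
                if backtrack(idx + 1):
                    return True
                del match[u], match[v]
        return False

    if not backtrack(0):
        raise SmilesParseError("cannot kekulize aromatic system")
    for b in mol.bonds:
        if b.order == "aromatic":
            b.kek_order = 2 if match.get(b.i) == b.j else 1


def _assign_hydrogens(mol: Molecule) -> None:
    for a in mol.atoms:
        bos = mol.bond_order_sum(a.index)
        if a._explicit_h is not None:
            allowed = _allowed_valences(a.element, a.formal_charge)
            if bos + a._explicit_h > max(allowed):
                raise SmilesParseError(
                    f"valence overflow at atom {a.index} ({a.element}): "
                    f"bond order sum {bos} + {a._explicit_h} H")
            a.implicit_h = a._explicit_h
        else:
            try:
                a.implicit_h = implicit_hydrogen_count(
                    a.element, a.formal_charge, bos)
            except ValueError as exc:
                raise SmilesParseError(f"atom {a.index}: {exc}") from exc


def ring_perception(mol: Molecule) -> list[list[int]]:
    """Smallest set of smallest rings; also flags in_ring on atoms/bonds.

    Ring membership of bonds is decided by bridge detection (a bond is in
    a ring iff it is not a bridge), which is exact; the returned cycle
    list is a minimum cycle basis.
    """
    g = mol.to_networkx()
    bridges = {frozenset(e) for e in nx.bridges(g)} if g.number_of_edges() else set()
    ring_atoms: set[int] = set()
    for b in mol.bonds:
        b.in_ring = frozenset((b.i, b.j)) not in bridges
        if b.in_ring:
            ring_atoms.update((b.i, b.j))
    for a in mol.atoms:
        a.in_ring = a.index in ring_atoms
    if not ring_atoms:
        return []
    return [sorted(cycle) for cycle in nx.minimum_cycle_basis(g)]


def parse_smiles(smiles: str, identifier: str = "") -> Molecule:
    """Parse a SMILES string into a validated :class:`Molecule`.

    Raises :class:`SmilesParseError` (with the offending position where
    known) for malformed input, unknown elements, stereochemistry,
    valence overflow, or un-kekulizable aromatic systems.
    """
    if not smiles:
        raise SmilesParseError("empty SMILES", 0)
    mol = _tokenize_atoms(smiles, identifier)
    ring_perception(mol)
    for a in mol.atoms:
        if a.aromatic and not a.in_ring:
            raise SmilesParseError(f"aromatic atom {a.index} not in a ring")
    _kekulize(mol)
    _assign_hydrogens(mol)
    if not mol.is_connected():
        raise SmilesParseError("molecule is not connected")
    return mol


# ---------------------------------------------------------------------------
# SMILES writer (non-canonical, dialect round-trips through parse_smiles)
# ---------------------------------------------------------------------------

def write_smiles(mol: Molecule) -> str:
    """Emit one valid SMILES spelling of the molecule (not canonical)."""
    n = len(mol.atoms)
    visited: set[int] = set()
    ring_marks: dict[frozenset[int], int] = {}
    tree_edges: set[frozenset[int]] = set()
    # DFS to find back edges
    order_stack = [0]
    parent: dict[int, int | None] = {0: None}
    seen = {0}
    while order_stack:
        u = order_stack.pop()
        for v in mol.neighbors(u):
            if v not in seen:
                seen.add(v)
                parent[v] = u
                tree_edges.add(frozenset((u, v)))
                order_stack.append(v)
    back_edges = [b for b in mol.bonds if frozenset((b.i, b.j)) not in tree_edges]
    for k, b in enumerate(back_edges, start=1):
        if k > 9:
            raise ValueError("too many rings for the simple writer")
        ring_marks[frozenset((b.i, b.j))] = k

    def bond_char(b: Bond, to_atom: int) -> str:
        if b.order == "double":
            return "="
        if b.order == "triple":
            return "#"
        return ""

    def atom_token(a: Atom) -> str:
        sym = a.element.lower() if a.aromatic else a.element
        bos = mol.bond_order_sum(a.index)
        default_h = None
        try:
            default_h = implicit_hydrogen_count(a.element, a.formal_charge, bos)
        except ValueError:
            pass
        needs_bracket = (a.formal_charge != 0 or a.implicit_h != default_h
                         or (a.aromatic and a.element not in
                             ("C", "N", "O", "S")))
        if a.aromatic and a.element == "N" and a.implicit_h > 0:
            needs_bracket = True
        if not needs_bracket:
            return sym
        h = f"H{a.implicit_h}" if a.implicit_h > 1 else ("H" if a.implicit_h else "")
        if a.formal_charge == 0:
            q = ""
        elif abs(a.formal_charge) == 1:
            q = "+" if a.formal_charge > 0 else "-"
        else:
            q = f"{'+' if a.formal_charge > 0 else '-'}{abs(a.formal_charge)}"
        return f"[{sym}{h}{q}]"

    out: list[str] = []

    def emit(u: int, from_bond: Bond | None) -> None:
        visited.add(u)
        if from_bond is not None:
            out.append(bond_char(from_bond, u))
        out.append(atom_token(mol.atoms[u]))
        for key, mark in ring_marks.items():
            if u in key:
                b = mol.bond_between(*tuple(key))
                other = next(iter(key - {u}))
                if other not in visited:
                    out.append(bond_char(b, other))
                out.append(str(mark))
        children = [v for v in mol.neighbors(u)
                    if v not in visited and frozenset((u, v)) in tree_edges]
        for idx, v in enumerate(children):
            last = idx == len(children) - 1
            if not last:
                out.append("(")
            emit(v, mol.bond_between(u, v))
            if not last:
                out.append(")")

    emit(0, None)
    if len(visited) != n:
        raise ValueError("writer requires a connected molecule")
    return "".join(out)


# ---------------------------------------------------------------------------
# .smi file I/O
# ---------------------------------------------------------------------------

def read_smi(path) -> list[Molecule]:
    """Read a .smi file: 'SMILES<whitespace>identifier' per line, '#' comments."""
    mols = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) < 2:
                raise ValueError(f"{path}:{ln}: expected 'SMILES identifier'")
            mols.append(parse_smiles(parts[0], identifier=parts[1]))
    return mols
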