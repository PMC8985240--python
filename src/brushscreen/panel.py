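"""The 14-monomer panel fixture and the synthetic-molecule generator.

The panel is the canonical input of the whole pipeline: 14 hydrophilic
monomers / polymer-brush repeating blocks (oxazoline, acrylamide,
vinylpyrrolidone, glycerol, acryloyl morpholine, dimethyl acrylamide,
hydroxypropyl and hydroxyethyl methacrylamide, sialic acid, carboxy-
betaine acrylamide/methacrylate, sulfobetaine methacrylate, methacryl-
oyloxyethyl phosphorylcholine and vinyl-pyridinio propanesulfonate).
It ships as a checksummed .smi file with per-entry provenance notes.

The generator emulates the panel's feature space for property-based
testing: small (<= 20 heavy atoms) organic molecules over {C,N,O,S,P}
with acyclic chains, at most one aliphatic or aromatic ring, carbonyl /
hydroxyl / amide / ester-like single-double bond patterns, and optional
zwitterion pairs (a quaternary ammonium N+ balanced by a carboxylate or
sulfonate group).  It does not sample realistic medicinal-chemistry
fragment distributions — it exercises the valence model and the graph
algorithms, nothing more.
"""

from __future__ import annotations

import hashlib
import random
from dataclasses import dataclass, field
from importlib import resources

from .molgraph import (Atom, Bond, Molecule, SmilesParseError,
                       _assign_hydrogens, _kekulize, parse_smiles,
                       ring_perception, write_smiles)

__all__ = [
    "MonomerPanel",
    "SyntheticMoleculeSpec",
    "PANEL_SHA256",
    "PANEL_ABBREVIATIONS",
    "load_panel",
    "generate_molecules",
    "perturb",
]

PANEL_SHA256 = "09d75b589e56a9e97780ee18ca4af6358d50f86b5d742171d7c7140655cba9d0"

PANEL_ABBREVIATIONS = ("OZ", "AA", "VP", "Gly", "AcM", "DMA", "HPMA",
                       "HEMA", "SA", "CBAA", "CBMA", "SBMA", "MPC", "VPPS")

#: The four pairwise MCS-Tanimoto coefficients the source study prints in
#: its Discussion; used as the reference set for semantics calibration.
PRINTED_TANIMOTO_REFERENCES: dict[tuple[str, str], float] = {
    ("HPMA", "HEMA"): 0.92,
    ("AA", "DMA"): 0.78,
    ("CBMA", "VPPS"): 0.21,
    ("SBMA", "CBMA"): 0.73,
}


@dataclass
class MonomerPanel:
    entries: list[tuple[str, str, str]]  # (abbreviation, full name, SMILES)

    def __post_init__(self):
        abbrevs = [e[0] for e in self.entries]
        if len(set(abbrevs)) != len(abbrevs):
            raise ValueError("duplicate abbreviations in panel")

    def molecules(self) -> list[Molecule]:
        return [parse_smiles(smi, identifier=abbr)
                for abbr, _, smi in self.entries]

    def __len__(self) -> int:
        return len(self.entries)


def load_panel() -> MonomerPanel:
    """Load the packaged 14-monomer fixture (checksum-verified)."""
    path = resources.files("brushscreen.data").joinpath("monomers.smi")
    raw = path.read_bytes()
    digest = hashlib.sha256(raw).hexdigest()
    if digest != PANEL_SHA256:
        raise ValueError(
            f"panel fixture checksum mismatch: {digest} != {PANEL_SHA256}")
    entries = []
    for line in raw.decode().splitlines():
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        body, _, comment = stripped.partition("#")
        parts = body.split()
        if len(parts) != 2:
            raise ValueError(f"malformed panel line: {line!r}")
        smi, abbr = parts
        name = comment.strip() or abbr
        entries.append((abbr, name, smi))
    panel = MonomerPanel(entries=entries)
    if tuple(e[0] for e in entries) != PANEL_ABBREVIATIONS:
        raise ValueError("panel fixture does not list the 14 expected monomers")
    panel.molecules()  # every SMILES must parse
    return panel


# ---------------------------------------------------------------------------
# synthetic molecules
# ---------------------------------------------------------------------------

@dataclass
class SyntheticMoleculeSpec:
    seed: int = 0
    n_molecules: int = 100
    heavy_atom_range: tuple[int, int] = (4, 18)
    element_weights: dict[str, float] = field(default_factory=lambda: {
        "C": 0.72, "N": 0.10, "O": 0.15, "S": 0.03, "P": 0.0})
    ring_probability: float = 0.35
    aromatic_ring_probability: float = 0.3  # of the rings, how many aromatic
    double_bond_probability: float = 0.25
    charge_pair_probability: float = 0.15
    group_probability: float = 0.2  # carboxyl/amide/sulfonic/phosphate arm

    def validate(self) -> None:
        lo, hi = self.heavy_atom_range
        if lo < 1 or hi < lo:
            raise ValueError(f"infeasible heavy_atom_range {self.heavy_atom_range}")
        for p in (self.ring_probability, self.aromatic_ring_probability,
                  self.double_bond_probability, self.charge_pair_probability,
                  self.group_probability):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0, 1]")
        if not self.element_weights or \
                any(w < 0 for w in self.element_weights.values()) or \
                sum(self.element_weights.values()) <= 0:
            raise ValueError("element_weights must be a non-negative, "
                             "non-degenerate distribution")
        unknown = set(self.element_weights) - {"C", "N", "O", "S", "P"}
        if unknown:
            raise ValueError(f"unsupported generator elements {unknown}")
        if self.charge_pair_probability > 0 and hi < 10:
            raise ValueError(
                "heavy_atom_range too small for zwitterion pairs "
                "(needs max >= 10)")


_BUDGET = {"C": 4, "N": 3, "O": 2, "S": 2, "P": 3}


class _Builder:
    """Incremental molecular-graph builder with a free-valence ledger."""

    def __init__(self):
        self.elements: list[str] = []
        self.charges: list[int] = []
        self.aromatic: list[bool] = []
        self.free: list[int] = []
        self.has_double: list[bool] = []
        self.bonds: list[list] = []  # [i, j, order, aromatic]

    def add_atom(self, element: str, charge: int = 0, aromatic: bool = False,
                 budget: int | None = None) -> int:
        self.elements.append(element)
        self.charges.append(charge)
        self.aromatic.append(aromatic)
        self.free.append(budget if budget is not None else _BUDGET[element])
        self.has_double.append(False)
        return len(self.elements) - 1

    def add_bond(self, i: int, j: int, order: int = 1,
                 aromatic: bool = False) -> None:
        cost = 1 if aromatic else order
        assert self.free[i] >= cost and self.free[j] >= cost
        self.free[i] -= cost
        self.free[j] -= cost
        self.bonds.append([i, j, order, aromatic])

    def to_molecule(self, identifier: str) -> Molecule:
        atoms = [Atom(index=k, element=e, formal_charge=q, aromatic=ar)
                 for k, (e, q, ar) in enumerate(
                     zip(self.elements, self.charges, self.aromatic))]
        names = {1: "single", 2: "double", 3: "triple"}
        bonds = [Bond(i=i, j=j, order="aromatic" if ar else names[o],
                      kek_order=0 if ar else o)
                 for i, j, o, ar in self.bonds]
        mol = Molecule(identifier, atoms, bonds)
        ring_perception(mol)
        _kekulize(mol)
        _assign_hydrogens(mol)
        return mol


def _build_one(rng: random.Random, spec: SyntheticMoleculeSpec,
               identifier: str) -> Molecule:
    lo, hi = spec.heavy_atom_range
    n_target = rng.randint(lo, hi)
    elements = sorted(spec.element_weights)
    weights = [spec.element_weights[e] for e in elements]
    b = _Builder()

    make_pair = spec.charge_pair_probability > 0 and \
        rng.random() < spec.charge_pair_probability
    # zwitterionic molecules are built on an acyclic scaffold (like the
    # betaine monomers); rings only for the neutral molecules
    make_ring = not make_pair and spec.ring_probability > 0 and \
        n_target >= 5 and rng.random() < spec.ring_probability
    aromatic_ring = make_ring and rng.random() < spec.aromatic_ring_probability

    if aromatic_ring:
        # benzene or pyridine; aromatic C may take one substituent
        with_n = rng.random() < 0.4
        ring = []
        for k in range(6):
            if with_n and k == 0:
                ring.append(b.add_atom("N", aromatic=True, budget=2))
            else:
                # 2 slots for the ring bonds + 1 for a substituent
                ring.append(b.add_atom("C", aromatic=True, budget=3))
        for k in range(6):
            b.add_bond(ring[k], ring[(k + 1) % 6], aromatic=True)
    elif make_ring:
        size = rng.randint(3, min(6, n_target))
        # all-carbon ring with at most one heteroatom member, so the ring
        # stays in the panel's feature space (no O-O / N-S ring bonds)
        members = ["C"] * size
        het = rng.choices(elements, weights)[0]
        if het in ("N", "O", "S"):
            members[-1] = het
        ring = [b.add_atom(e) for e in members]
        for k in range(size):
            b.add_bond(ring[k], ring[(k + 1) % size])
    else:
        b.add_atom("C")

    # decorations go on early, while free valence is guaranteed; the
    # sampled size target stretches to cover the arm but never past the
    # configured maximum (the pair needs <= 10 atoms incl. scaffold)
    _, hi = spec.heavy_atom_range
    if make_pair:
        _attach_charge_pair(rng, b)
        n_target = max(n_target, len(b.elements))
    elif spec.group_probability and rng.random() < spec.group_probability:
        room = hi - len(b.elements)
        kind = _attach_group(rng, b, room)
        if kind:
            n_target = max(n_target, len(b.elements))

    while len(b.elements) < n_target:
        sites = [i for i in range(len(b.elements)) if b.free[i] >= 1]
        if not sites:
            break
        host = rng.choice(sites)
        el = rng.choices(elements, weights)[0]
        # heteroatoms bond only to carbon: keeps every environment inside
        # the packaged contribution tables (no N-O, O-O, S-N, P-N motifs)
        if b.elements[host] != "C" and el != "C":
            el = "C"
        if el == "P":
            el = "C"  # free phosphorus only enters via phosphate arms
        new = b.add_atom(el)
        b.add_bond(host, new)

    # promote some single bonds to double where both ends have spare
    # valence; only C=C, C=O and C=N, and no cumulated doubles
    for bond in b.bonds:
        i, j, order, ar = bond
        if ar or order != 1 or b.aromatic[i] or b.aromatic[j]:
            continue
        pair = {b.elements[i], b.elements[j]}
        if not (pair <= {"C", "N", "O"} and "C" in pair):
            continue
        if b.has_double[i] or b.has_double[j]:
            continue
        if b.free[i] >= 1 and b.free[j] >= 1 and \
                rng.random() < spec.double_bond_probability:
            bond[2] = 2
            b.free[i] -= 1
            b.free[j] -= 1
            b.has_double[i] = b.has_double[j] = True

    mol = b.to_molecule(identifier)
    return mol


_GROUP_SIZES = {"carboxyl": 3, "amide": 3, "sulfonic": 4, "phosphate": 7}


def _attach_group(rng: random.Random, b: _Builder, room: int) -> str | None:
    """Decorate a carbon with a common polar group (carboxyl, primary
    amide, sulfonic acid or dialkyl-phosphate arm) if it fits in `room`
    extra atoms; returns the group kind or None."""
    hosts = [i for i in range(len(b.elements))
             if b.free[i] >= 1 and b.elements[i] == "C"]
    fits = [k for k, size in _GROUP_SIZES.items() if size <= room]
    if not hosts or not fits:
        return None
    host = rng.choice(hosts)
    kind = rng.choice(fits)
    if kind in ("carboxyl", "amide"):
        c = b.add_atom("C")
        b.add_bond(host, c)
        o = b.add_atom("O")
        b.add_bond(c, o, order=2)
        x = b.add_atom("O" if kind == "carboxyl" else "N")
        b.add_bond(c, x)
        b.has_double[c] = True
    elif kind == "sulfonic":
        s = b.add_atom("S", budget=6)
        b.add_bond(host, s)
        for _ in range(2):
            o = b.add_atom("O")
            b.add_bond(s, o, order=2)
        o = b.add_atom("O")
        b.add_bond(s, o)
    else:  # neutral dialkyl phosphate: host-O-P(=O)(OH)-O-CH3
        o0 = b.add_atom("O")
        b.add_bond(host, o0)
        p = b.add_atom("P", budget=5)
        b.add_bond(o0, p)
        od = b.add_atom("O")
        b.add_bond(p, od, order=2)
        oh = b.add_atom("O")
        b.add_bond(p, oh)
        o2 = b.add_atom("O")
        b.add_bond(p, o2)
        c = b.add_atom("C")
        b.add_bond(o2, c)
    return kind


def _attach_charge_pair(rng: random.Random, b: _Builder) -> None:
    """Quaternary ammonium + carboxylate/sulfonate: a net-neutral zwitterion.

    Both groups hang off one fresh carbon arm, so attachment is always
    feasible right after scaffold construction (every scaffold keeps at
    least one free slot on a carbon or on the chain-start atom).
    """
    hosts = [i for i in range(len(b.elements)) if b.free[i] >= 1]
    arm = b.add_atom("C")
    b.add_bond(rng.choice(hosts), arm)
    if rng.random() < 0.5:  # carboxylate
        c = b.add_atom("C")
        b.add_bond(arm, c)
        o1 = b.add_atom("O")
        b.add_bond(c, o1, order=2)
        o2 = b.add_atom("O", charge=-1, budget=1)
        b.add_bond(c, o2)
    else:  # sulfonate
        s = b.add_atom("S", budget=6)
        b.add_bond(arm, s)
        for _ in range(2):
            o = b.add_atom("O")
            b.add_bond(s, o, order=2)
        o = b.add_atom("O", charge=-1, budget=1)
        b.add_bond(s, o)
    n = b.add_atom("N", charge=1, budget=4)
    b.add_bond(arm, n)
    while b.free[n] > 0:
        c = b.add_atom("C")
        b.add_bond(n, c)


def generate_molecules(spec: SyntheticMoleculeSpec) -> list[Molecule]:
    """Seeded random molecules; every output round-trips through the
    SMILES parser and satisfies the valence model by construction."""
    spec.validate()
    rng = random.Random(spec.seed)
    out = []
    for k in range(spec.n_molecules):
        mol = _build_one(rng, spec, identifier=f"syn{spec.seed}_{k}")
        smi = write_smiles(mol)
        reparsed = parse_smiles(smi, identifier=mol.identifier)
        if reparsed.formula() != mol.formula():  # pragma: no cover
            raise AssertionError(
                f"generator round-trip failed for {mol.identifier}: "
                f"{mol.formula()} != {reparsed.formula()} ({smi})")
        out.append(reparsed)
    return out


# ---------------------------------------------------------------------------
# single-edit perturbations (feed MCS monotonicity tests)
# ---------------------------------------------------------------------------

def perturb(mol: Molecule, op: str) -> Molecule:
    """Single-edit neighbour of a molecule.

    delete_terminal_atom: remove the highest-index degree-1 atom.
    mutate_element: change the first eligible C into N (valence permits).
    """
    if op == "delete_terminal_atom":
        terminals = [a.index for a in mol.atoms
                     if mol.degree(a.index) == 1 and not a.aromatic]
        if len(mol) < 2 or not terminals:
            raise ValueError("no deletable terminal atom")
        victim = terminals[-1]
        keep = [a for a in mol.atoms if a.index != victim]
        remap = {a.index: k for k, a in enumerate(keep)}
        atoms = [Atom(index=remap[a.index], element=a.element,
                      formal_charge=a.formal_charge, aromatic=a.aromatic)
                 for a in keep]
        bonds = [Bond(i=remap[b.i], j=remap[b.j], order=b.order,
                      kek_order=b.kek_order)
                 for b in mol.bonds if victim not in (b.i, b.j)]
        out = Molecule(f"{mol.identifier}~del", atoms, bonds)
        ring_perception(out)
        _kekulize(out)
        _assign_hydrogens(out)
        return out
    if op == "mutate_element":
        for a in mol.atoms:
            if a.element == "C" and not a.aromatic and a.formal_charge == 0 \
                    and mol.bond_order_sum(a.index) <= 3:
                atoms = [Atom(index=x.index,
                              element="N" if x.index == a.index else x.element,
                              formal_charge=x.formal_charge, aromatic=x.aromatic)
                         for x in mol.atoms]
                bonds = [Bond(i=bd.i, j=bd.j, order=bd.order,
                              kek_order=bd.kek_order) for bd in mol.bonds]
                out = Molecule(f"{mol.identifier}~mut", atoms, bonds)
                ring_perception(out)
                _kekulize(out)
                _assign_hydrogens(out)
                return out
        raise ValueError("no mutable carbon")
    raise ValueError(f"unknown perturbation {op!r}")


# make SmilesParseError importable from here for callers catching generator
# round-trip issues
_ = SmilesParseError
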