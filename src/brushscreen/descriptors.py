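"""Physicochemical descriptor vectors and rule-based drug-likeness reports.

All group-contribution tables (Ertl TPSA, Wildman–Crippen logP/MR), the
ESOL solubility coefficients and every rule threshold are packaged in the
versioned ``data/constants.json`` file, not hard-coded here, so that the
numeric basis of the pipeline is auditable in one place.

The lipophilicity estimate is the atom-contribution WLOGP model alone
(a single reproducible table-driven model rather than a multi-predictor
consensus).  Hydrogen-bond acceptor/donor counts use an explicit pinned
definition: HBA = N and O atoms excluding amide-type N, pyrrole-type N
and positively charged N; HBD = N/O atoms bearing at least one hydrogen.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources

import pandas as pd

from .molgraph import Molecule

__all__ = [
    "CONSTANTS",
    "DescriptorVector",
    "RuleReport",
    "DescriptorError",
    "molecular_weight",
    "fraction_csp3",
    "count_hba",
    "count_hbd",
    "rotatable_bonds",
    "tpsa",
    "wlogp",
    "molar_refractivity",
    "esol_logs",
    "aromatic_proportion",
    "compute_descriptors",
    "evaluate_rules",
    "bioavailability_score",
    "descriptor_table",
]


def _load_constants() -> dict:
    with resources.files("brushscreen.data").joinpath("constants.json").open() as fh:
        return json.load(fh)


CONSTANTS = _load_constants()

_HETERO = {"N", "O", "S", "P", "F", "Cl", "Br"}


class DescriptorError(ValueError):
    """An atom environment outside the packaged contribution tables."""


@dataclass
class DescriptorVector:
    """Named physicochemical profile of one molecule.

    The ten public descriptors mirror a SwissADME-style physicochemical
    panel; the trailing auxiliary fields feed the rule filters and the
    solubility model.
    """

    identifier: str
    molecular_weight: float
    heavy_atoms: int
    fraction_csp3: float
    hba: int
    hbd: int
    rotatable_bonds: int
    tpsa: float
    wlogp: float
    molar_refractivity: float
    esol_logs: float
    # auxiliary (not part of the 10-descriptor table)
    rings: int = 0
    carbons: int = 0
    heteroatoms: int = 0
    aromatic_proportion: float = 0.0

    FIELDS = ("molecular_weight", "heavy_atoms", "fraction_csp3", "hba",
              "hbd", "rotatable_bonds", "tpsa", "wlogp",
              "molar_refractivity", "esol_logs")


@dataclass
class RuleReport:
    rule_name: str
    violations: list[str] = field(default_factory=list)
    passes: bool = True
    bioavailability_score: float = 0.0


# ---------------------------------------------------------------------------
# simple counts
# ---------------------------------------------------------------------------

def molecular_weight(mol: Molecule) -> float:
    w = CONSTANTS["atomic_weights"]
    total = sum(w[a.element] for a in mol.atoms) + w["H"] * mol.total_h()
    return round(total, 2)


def fraction_csp3(mol: Molecule) -> float:
    carbons = [a for a in mol.atoms if a.element == "C"]
    if not carbons:
        raise DescriptorError(f"{mol.identifier}: no carbon atoms, Fsp3 undefined")
    sp3 = sum(
        1 for a in carbons
        if not a.aromatic and all(
            b.kek_order == 1 for b in (mol.bond_between(a.index, nb)
                                       for nb in mol.neighbors(a.index))))
    return sp3 / len(carbons)


def _is_amide_type_n(mol: Molecule, idx: int) -> bool:
    """N single-bonded to a carbon that is double-bonded to O or S."""
    for nb in mol.neighbors(idx):
        if mol.atoms[nb].element != "C":
            continue
        if mol.bond_between(idx, nb).kek_order != 1:
            continue
        for nb2 in mol.neighbors(nb):
            b = mol.bond_between(nb, nb2)
            if b.kek_order == 2 and mol.atoms[nb2].element in ("O", "S"):
                return True
    return False


def _is_pyrrole_type_n(mol: Molecule, idx: int) -> bool:
    a = mol.atoms[idx]
    return a.aromatic and (a.implicit_h > 0 or mol.degree(idx) == 3)


def count_hba(mol: Molecule) -> int:
    n = 0
    for a in mol.atoms:
        if a.element not in ("N", "O"):
            continue
        if a.element == "N":
            if a.formal_charge > 0:
                continue
            if _is_pyrrole_type_n(mol, a.index) or _is_amide_type_n(mol, a.index):
                continue
        n += 1
    return n


def count_hbd(mol: Molecule) -> int:
    return sum(1 for a in mol.atoms
               if a.element in ("N", "O") and a.implicit_h > 0)


def rotatable_bonds(mol: Molecule) -> int:
    """Acyclic single bonds between two non-terminal heavy atoms,
    excluding amide C-N bonds."""
    n = 0
    for b in mol.bonds:
        if b.order != "single" or b.in_ring:
            continue
        if mol.degree(b.i) < 2 or mol.degree(b.j) < 2:
            continue
        pair = {mol.atoms[b.i].element, mol.atoms[b.j].element}
        if pair == {"C", "N"}:
            c = b.i if mol.atoms[b.i].element == "C" else b.j
            if any(mol.bond_between(c, nb).kek_order == 2
                   and mol.atoms[nb].element == "O"
                   for nb in mol.neighbors(c)):
                continue  # amide
        n += 1
    return n


def aromatic_proportion(mol: Molecule) -> float:
    return sum(1 for a in mol.atoms if a.aromatic) / len(mol.atoms)


# ---------------------------------------------------------------------------
# Ertl TPSA (extended with S/P environments)
# ---------------------------------------------------------------------------

def _in_three_ring(mol: Molecule, idx: int) -> bool:
    nbs = mol.neighbors(idx)
    return any(mol.bond_between(u, v) is not None
               for i, u in enumerate(nbs) for v in nbs[i + 1:])


def _tpsa_label(mol: Molecule, idx: int) -> str:
    a = mol.atoms[idx]
    el = a.element
    h = a.implicit_h
    q = a.formal_charge
    if a.aromatic:
        deg = mol.degree(idx)
        if el == "N":
            if q > 0:
                if h:
                    return "nH+_ar"
                return "n+_ar2s" if any(
                    mol.bond_between(idx, nb).order != "aromatic"
                    for nb in mol.neighbors(idx)) else "n+_ar3"
            if h:
                return "nH_ar"
            if deg == 2:
                return "n_ar2"
            return "n_ar2s" if any(
                mol.bond_between(idx, nb).order != "aromatic"
                for nb in mol.neighbors(idx)) else "n_ar3"
        if el == "O":
            return "o_ar"
        if el == "S":
            return "s_ar"
        raise DescriptorError(
            f"{mol.identifier}: no TPSA fragment for aromatic {el} at atom {idx}")
    orders = sorted(b.kek_order for b in
                    (mol.bond_between(idx, nb) for nb in mol.neighbors(idx)))
    s = orders.count(1)
    d = orders.count(2)
    t = orders.count(3)
    key = None
    if el == "N":
        if q == 0:
            if t == 1 and d == 1:
                key = "N_dt"
            elif t == 1:
                key = "N_t"
            elif d == 2:
                key = "N_ssdd"
            elif d == 1:
                key = "NH_d" if h else "N_sd"
            elif h == 0 and s == 3:
                key = "N_ring3" if _in_three_ring(mol, idx) else "N_sss"
            elif h == 1 and s == 2:
                key = "NH_ring3" if _in_three_ring(mol, idx) else "NH_ss"
            elif h == 2 and s == 1:
                key = "NH2_s"
        elif q == 1:
            if t == 1:
                key = "N+_st"
            elif d == 1:
                key = {0: "N+_ssd", 1: "NH+_sd", 2: "NH2+_d"}.get(h)
            else:
                key = {0: "N+_ssss", 1: "NH+_sss", 2: "NH2+_ss",
                       3: "NH3+_s"}.get(h)
    elif el == "O":
        if q == -1:
            key = "O-_s"
        elif d == 1:
            key = "O_d"
        elif h >= 1:
            key = "OH_s"
        elif s == 2:
            key = "O_ss_ring3" if _in_three_ring(mol, idx) else "O_ss"
    elif el == "S":
        if d == 2:
            key = "S_ssdd"
        elif d == 1 and s == 2:
            key = "S_ssd"
        elif d == 1:
            key = "S_d"
        elif h == 1:
            key = "SH_s"
        elif s == 2:
            key = "S_ss"
    elif el == "P":
        if d == 1 and s == 3:
            key = "P_sssd"
        elif d == 1 and h == 1:
            key = "PH_ssd"
        elif d == 1:
            key = "P_sd"
        elif s == 3:
            key = "P_sss"
    if key is None or key not in CONSTANTS["tpsa"]:
        raise DescriptorError(
            f"{mol.identifier}: no TPSA fragment for {el} at atom {idx} "
            f"(charge {q:+d}, {h}H, bond orders {orders})")
    return key


def tpsa(mol: Molecule) -> float:
    table = CONSTANTS["tpsa"]
    total = 0.0
    for a in mol.atoms:
        if a.element in ("N", "O", "S", "P"):
            total += table[_tpsa_label(mol, a.index)]
    return round(total, 2)


# ---------------------------------------------------------------------------
# Wildman-Crippen atom typing (WLOGP, molar refractivity)
# ---------------------------------------------------------------------------

def _crippen_carbon(mol: Molecule, idx: int) -> str:
    a = mol.atoms[idx]
    nbs = mol.neighbors(idx)
    nb_atoms = [mol.atoms[j] for j in nbs]
    if a.aromatic:
        exo = [n for n in nb_atoms
               if mol.bond_between(idx, n.index).order != "aromatic"]
        if not exo:
            if mol.degree(idx) > 2:
                raise DescriptorError(
                    f"{mol.identifier}: fused-aromatic carbon {idx} not typed")
            return "C18"  # aromatic C-H
        sub = exo[0]
        if sub.element == "C":
            return "C21"
        if sub.element == "N":
            return "C22"
        if sub.element == "O":
            return "C23"
        if sub.element == "S":
            return "C24"
        raise DescriptorError(
            f"{mol.identifier}: aromatic C {idx} with {sub.element} substituent")
    orders = [mol.bond_between(idx, j).kek_order for j in nbs]
    if 3 in orders:
        return "C7"
    if 2 in orders:
        for j, o in zip(nbs, orders):
            if o == 2 and mol.atoms[j].element in _HETERO:
                return "C5"  # C=heteroatom (carbonyl, imine carbon, ...)
        if any(n.aromatic for n in nb_atoms):
            return "C26"  # vinyl carbon attached to an aromatic system
        return "C6"
    # sp3
    if any(n.aromatic for n in nb_atoms):
        h = a.implicit_h
        if h >= 3:
            arom_nb = next(n for n in nb_atoms if n.aromatic)
            return "C8" if arom_nb.element == "C" else "C9"
        if h == 2:
            return "C10"
        if h == 1:
            return "C11"
        return "C12"  # quaternary benzylic
    if any(n.element in _HETERO for n in nb_atoms):
        return "C3" if a.implicit_h >= 2 else "C4"
    return "C1" if a.implicit_h >= 2 else "C2"


def _crippen_nitrogen(mol: Molecule, idx: int) -> str:
    a = mol.atoms[idx]
    if a.aromatic:
        return "N12" if a.formal_charge > 0 else "N11"
    if a.formal_charge > 0:
        if a.implicit_h == 0 and mol.degree(idx) == 4:
            return "N13"  # quaternary ammonium
        raise DescriptorError(
            f"{mol.identifier}: protonated amine at atom {idx} not typed")
    orders = [mol.bond_between(idx, j).kek_order for j in mol.neighbors(idx)]
    if 3 in orders:
        return "N9"  # nitrile
    if 2 in orders:
        return "N5" if a.implicit_h else "N6"  # imine
    arom_nb = any(mol.atoms[j].aromatic for j in mol.neighbors(idx))
    if a.implicit_h >= 2:
        return "N3" if arom_nb else "N1"
    if a.implicit_h == 1:
        return "N4" if arom_nb else "N2"
    return "N8" if arom_nb else "N7"


def _crippen_oxygen(mol: Molecule, idx: int) -> str:
    a = mol.atoms[idx]
    if a.aromatic:
        return "O1"
    nbs = mol.neighbors(idx)
    nb_el = [mol.atoms[j].element for j in nbs]
    orders = [mol.bond_between(idx, j).kek_order for j in nbs]
    if "S" in nb_el and (2 in orders or a.formal_charge < 0):
        return "O6"  # any O on S(IV)/S(VI)
    if a.formal_charge < 0:
        if not nbs:
            return "O2"  # hydroxide
        c = nbs[0]
        if mol.atoms[c].element == "C" and any(
                mol.bond_between(c, k).kek_order == 2
                and mol.atoms[k].element == "O" for k in mol.neighbors(c)):
            return "O12"  # carboxylate O-
        return "O7"  # other charged O (e.g. phosphate O-)
    if 2 in orders:
        c = nbs[orders.index(2)]
        if mol.atoms[c].element != "C":
            return "OS"  # O= on P, etc: catch-all oxygen
        c_nbs = [k for k in mol.neighbors(c) if k != idx]
        het_el = [mol.atoms[k].element for k in c_nbs
                  if mol.atoms[k].element != "C"]
        carbons = len(c_nbs) - len(het_el)
        if len(het_el) >= 2:
            return "O11"  # carbonyl flanked by two heteroatoms
        if het_el and carbons == 0 and het_el[0] in ("S", "P"):
            return "OS"   # thioformyl-like carbonyl: catch-all
        conj = any(mol.atoms[k].aromatic for k in c_nbs)
        return "O10" if conj else "O9"
    if a.implicit_h >= 1:
        return "O2"  # alcohol / phenol / acid OH / water
    arom_nb = any(mol.atoms[j].aromatic for j in nbs)
    if arom_nb:
        return "O4"  # aromatic ether (wins over O-P)
    if "P" in nb_el:
        return "O3"  # alkyl phosphate ester O
    return "O3"


def _crippen_type(mol: Molecule, idx: int) -> str:
    el = mol.atoms[idx].element
    if el == "C":
        return _crippen_carbon(mol, idx)
    if el == "N":
        return _crippen_nitrogen(mol, idx)
    if el == "O":
        return _crippen_oxygen(mol, idx)
    if el == "S":
        a = mol.atoms[idx]
        if a.aromatic:
            return "S3"
        # S(IV)/S(VI) centres (sulfoxide, sulfone, sulfonate) are S2;
        # thiols/thioethers/thiocarbonyls stay S1
        if any(mol.bond_between(idx, j).kek_order == 2
               and mol.atoms[j].element == "O"
               for j in mol.neighbors(idx)):
            return "S2"
        return "S1"
    if el == "P":
        return "P"
    if el in ("F", "Cl", "Br"):
        return el
    raise DescriptorError(f"{mol.identifier}: untypable element {el} at atom {idx}")


def _hydrogen_type(mol: Molecule, idx: int) -> str:
    el = mol.atoms[idx].element
    if el == "C":
        return "H1"
    if el == "N":
        return "H3"
    if el == "O":
        a = mol.atoms[idx]
        if a.formal_charge < 0:
            return "HS"
        for j in mol.neighbors(idx):
            nb = mol.atoms[j]
            if nb.element in ("O", "S"):
                return "H4"  # peroxide / O-S acid hydrogens
            if nb.element == "C" and not nb.aromatic:
                for k in mol.neighbors(j):
                    b = mol.bond_between(j, k)
                    if k != idx and b.order == "double" and \
                            mol.atoms[k].element in ("C", "N", "O", "S"):
                        return "H4"  # carboxylic acid / enol
        return "H2"  # alcohol-type
    return "H2"  # thiol etc.


def _crippen_sum(mol: Molecule, which: int) -> float:
    table = CONSTANTS["crippen"]
    total = 0.0
    for a in mol.atoms:
        label = _crippen_type(mol, a.index)
        total += table[label][which]
        if a.implicit_h:
            total += a.implicit_h * table[_hydrogen_type(mol, a.index)][which]
    return total


def wlogp(mol: Molecule) -> float:
    """Wildman-Crippen atom-contribution estimate of log P(octanol/water)."""
    return round(_crippen_sum(mol, 0), 4)


def molar_refractivity(mol: Molecule) -> float:
    return round(_crippen_sum(mol, 1), 4)


# ---------------------------------------------------------------------------
# ESOL solubility
# ---------------------------------------------------------------------------

def esol_logs(mol: Molecule, desc: "DescriptorVector | None" = None) -> float:
    """Delaney ESOL linear estimate of aqueous solubility (log mol/L).

    logS = 0.16 - 0.63*WLOGP - 0.0062*MW + 0.066*RB - 0.74*AP, with AP the
    aromatic-atom proportion and RB the rotatable-bond count.
    """
    c = CONSTANTS["esol"]
    if desc is not None:
        lp, mw, rb = desc.wlogp, desc.molecular_weight, desc.rotatable_bonds
        ap = desc.aromatic_proportion
    else:
        lp, mw = wlogp(mol), molecular_weight(mol)
        rb, ap = rotatable_bonds(mol), aromatic_proportion(mol)
    val = (c["intercept"] + c["wlogp"] * lp + c["mw"] * mw
           + c["rotatable_bonds"] * rb + c["aromatic_proportion"] * ap)
    return round(val, 4)


# ---------------------------------------------------------------------------
# assembly, rules, tables
# ---------------------------------------------------------------------------

def compute_descriptors(mol: Molecule) -> DescriptorVector:
    from .molgraph import ring_perception
    rings = ring_perception(mol)
    vec = DescriptorVector(
        identifier=mol.identifier,
        molecular_weight=molecular_weight(mol),
        heavy_atoms=mol.heavy_atom_count,
        fraction_csp3=round(fraction_csp3(mol), 4),
        hba=count_hba(mol),
        hbd=count_hbd(mol),
        rotatable_bonds=rotatable_bonds(mol),
        tpsa=tpsa(mol),
        wlogp=wlogp(mol),
        molar_refractivity=molar_refractivity(mol),
        esol_logs=0.0,
        rings=len(rings),
        carbons=sum(1 for a in mol.atoms if a.element == "C"),
        heteroatoms=sum(1 for a in mol.atoms if a.element != "C"),
        aromatic_proportion=round(aromatic_proportion(mol), 4),
    )
    vec.esol_logs = esol_logs(mol, vec)
    return vec


def _rule_violations(rule: dict, desc: DescriptorVector) -> list[str]:
    out = []
    for label, cond in rule["conditions"].items():
        value = getattr(desc, cond[0])
        op = cond[1]
        if op == "<=":
            ok = value <= cond[2]
        elif op == ">":
            ok = value > cond[2]
        elif op == "between":
            ok = cond[2] <= value <= cond[3]
        else:  # pragma: no cover - constants file is under our control
            raise ValueError(f"unknown operator {op!r}")
        if not ok:
            out.append(label)
    return out


def _is_acid(mol: Molecule) -> bool:
    """Carries (or would carry at physiological pH) a negative charge."""
    if any(a.formal_charge < 0 for a in mol.atoms):
        return True
    for a in mol.atoms:  # neutral acids: O-H on C=O, S(=O), P(=O)
        if a.element == "O" and a.implicit_h:
            for j in mol.neighbors(a.index):
                nb = mol.atoms[j]
                if nb.element in ("C", "S", "P") and any(
                        mol.bond_between(j, k).kek_order == 2
                        and mol.atoms[k].element == "O"
                        for k in mol.neighbors(j)):
                    return True
    return False


def bioavailability_score(desc: DescriptorVector, mol: Molecule) -> float:
    """Abbott bioavailability score (probability-of-F>10% class)."""
    cfg = CONSTANTS["bioavailability"]
    if _is_acid(mol):
        for bound, score in cfg["anion_tpsa_bins"]:
            if bound is None or desc.tpsa <= bound:
                return score
    lip = [r for r in evaluate_rules(desc, _score=False)
           if r.rule_name == "Lipinski"][0]
    return cfg["pass"] if lip.passes else cfg["fail"]


def evaluate_rules(desc: DescriptorVector, mol: Molecule | None = None,
                   _score: bool = True) -> list[RuleReport]:
    """Evaluate the packaged drug-likeness scales on a descriptor vector.

    Lipinski passes with at most one violation; every other scale allows
    none.  When the molecule is supplied the Abbott bioavailability score
    is attached to each report.
    """
    reports = []
    score = bioavailability_score(desc, mol) if (mol is not None and _score) else 0.0
    for name, rule in CONSTANTS["rules"].items():
        v = _rule_violations(rule, desc)
        reports.append(RuleReport(
            rule_name=name, violations=v,
            passes=len(v) <= rule["allowed_violations"],
            bioavailability_score=score))
    return reports


def descriptor_table(panel: list[Molecule]) -> pd.DataFrame:
    """One row per molecule, one column per descriptor, input order kept."""
    rows = []
    for mol in panel:
        try:
            d = compute_descriptors(mol)
        except Exception as exc:
            raise DescriptorError(
                f"descriptor computation failed for {mol.identifier!r}: {exc}"
            ) from exc
        rows.append({"identifier": d.identifier,
                     **{f: getattr(d, f) for f in DescriptorVector.FIELDS}})
    df = pd.DataFrame(rows, columns=["identifier", *DescriptorVector.FIELDS])
    return df.set_index("identifier")


def rules_table(panel: list[Molecule]) -> pd.DataFrame:
    rows = []
    for mol in panel:
        d = compute_descriptors(mol)
        row: dict = {"identifier": mol.identifier}
        for rep in evaluate_rules(d, mol):
            row[f"{rep.rule_name}_pass"] = rep.passes
            row[f"{rep.rule_name}_violations"] = ";".join(rep.violations)
            row["bioavailability_score"] = rep.bioavailability_score
        rows.append(row)
    return pd.DataFrame(rows).set_index("identifier")
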