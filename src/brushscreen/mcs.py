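"""Maximum common substructure (MCS) and MCS-based Tanimoto similarity.

The similarity coefficient between two molecules is the Jaccard/Tanimoto
ratio c/(a+b+c), where c counts the features shared by both molecules
(the features covered by their maximum common substructure) and a, b the
features unique to each.  Features are heavy atoms by default; an
atoms+bonds variant is available for calibration.

The MCS here is the *connected, induced* maximum common subgraph, found
exactly by backtracking over the modular product of the two molecular
graphs (Koch-style c-clique branch and bound).  Exactness keeps every
result deterministic; a hard size guard (40 heavy atoms) replaces any
timeout heuristic.  Ties between maximum mappings are broken by the
lexicographically smallest mapping, so repeated runs are bit-identical.

Atom matching is element identity (optionally charge-sensitive); bond
matching is either order-blind ("any") or exact on kekulized integer
orders ("exact") — aromatic bonds compare through their kekule
assignment, which makes a pyridinium ring locally comparable to an
aliphatic chain only through its formally single bonds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .molgraph import Molecule

__all__ = [
    "MatchSemantics",
    "MCSResult",
    "SimilarityMatrix",
    "DEFAULT_SEMANTICS",
    "SEMANTICS_GRID",
    "mcs",
    "tanimoto_matrix",
    "calibrate_semantics",
    "CalibrationResult",
]

MAX_EXACT_ATOMS = 40


@dataclass(frozen=True)
class MatchSemantics:
    """Active match rules for the MCS search.

    feature_unit: "atoms" or "atoms+bonds" — the unit in which c, a, b
        are counted.
    charge_sensitive: require equal formal charge for matched atoms.
    bond_order: "any" (orders ignored) or "exact" (kekulized orders must
        be equal).
    """

    feature_unit: str = "atoms"
    charge_sensitive: bool = False
    bond_order: str = "any"

    def __post_init__(self):
        if self.feature_unit not in ("atoms", "atoms+bonds"):
            raise ValueError(f"unknown feature unit {self.feature_unit!r}")
        if self.bond_order not in ("any", "exact"):
            raise ValueError(f"unknown bond order mode {self.bond_order!r}")


DEFAULT_SEMANTICS = MatchSemantics()

#: Calibration grid in deterministic preference order (earlier wins ties).
SEMANTICS_GRID = tuple(
    MatchSemantics(feature_unit=u, charge_sensitive=c, bond_order=b)
    for u in ("atoms", "atoms+bonds")
    for c in (False, True)
    for b in ("exact", "any"))


@dataclass
class MCSResult:
    mapping: list[tuple[int, int]]
    c: int
    a: int
    b: int
    tanimoto: float
    matched_bonds: int = 0


@dataclass
class SimilarityMatrix:
    identifiers: list[str]
    values: np.ndarray

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.identifiers,
                            columns=self.identifiers)

    def to_long(self) -> pd.DataFrame:
        rows = []
        n = len(self.identifiers)
        for i in range(n):
            for j in range(i + 1, n):
                rows.append({"idA": self.identifiers[i],
                             "idB": self.identifiers[j],
                             "tanimoto": self.values[i, j]})
        return pd.DataFrame(rows, columns=["idA", "idB", "tanimoto"])

    def pair(self, ida: str, idb: str) -> float:
        i = self.identifiers.index(ida)
        j = self.identifiers.index(idb)
        return float(self.values[i, j])


# ---------------------------------------------------------------------------
# modular-product construction and c-clique search
# ---------------------------------------------------------------------------

def _atom_match(a, b, sem: MatchSemantics) -> bool:
    if a.element != b.element:
        return False
    return (not sem.charge_sensitive) or a.formal_charge == b.formal_charge


def _bond_match(ba, bb, sem: MatchSemantics) -> bool:
    return sem.bond_order == "any" or ba.kek_order == bb.kek_order


def mcs(molA: Molecule, molB: Molecule,
        semantics: MatchSemantics = DEFAULT_SEMANTICS) -> MCSResult:
    """Exact connected induced MCS of two molecules.

    Raises ValueError when either molecule exceeds the exact-search size
    guard (too large for exact MCS).
    """
    nA, nB = len(molA), len(molB)
    if nA > MAX_EXACT_ATOMS or nB > MAX_EXACT_ATOMS:
        raise ValueError(
            f"too large for exact MCS: {max(nA, nB)} heavy atoms "
            f"(guard {MAX_EXACT_ATOMS})")

    # modular product vertices: compatible atom pairs, lexicographic order
    verts: list[tuple[int, int]] = [
        (i, j) for i in range(nA) for j in range(nB)
        if _atom_match(molA.atoms[i], molB.atoms[j], semantics)]
    nv = len(verts)
    if nv == 0:
        return _result([], 0, molA, molB, semantics)

    # adjacency bitsets: compat (c or d edge) and c-only
    compat = [0] * nv
    cadj = [0] * nv
    for p in range(nv):
        i, j = verts[p]
        for q in range(p + 1, nv):
            k, l = verts[q]
            if i == k or j == l:
                continue
            eA = molA.bond_between(i, k)
            eB = molB.bond_between(j, l)
            if eA is None and eB is None:
                compat[p] |= 1 << q
                compat[q] |= 1 << p
            elif eA is not None and eB is not None and \
                    _bond_match(eA, eB, semantics):
                compat[p] |= 1 << q
                compat[q] |= 1 << p
                cadj[p] |= 1 << q
                cadj[q] |= 1 << p

    count_bonds = semantics.feature_unit == "atoms+bonds"
    best_atoms = 0
    best_bonds = 0
    best_mapping: tuple[tuple[int, int], ...] = ()
    max_possible = min(nA, nB)

    def bitcount(x: int) -> int:
        return x.bit_count()

    def better(atoms: int, bonds: int, mapping: list[int]) -> bool:
        if count_bonds:
            sc, bs = atoms + bonds, best_atoms + best_bonds
        else:
            sc, bs = atoms, best_atoms
        if sc != bs:
            return sc > bs
        return tuple(sorted(verts[v] for v in mapping)) < best_mapping

    def extend(clique: list[int], nbonds: int, P: int, D: int) -> None:
        nonlocal best_atoms, best_bonds, best_mapping
        if better(len(clique), nbonds, clique):
            best_atoms = len(clique)
            best_bonds = nbonds
            best_mapping = tuple(sorted(verts[v] for v in clique))
        # branch and bound: '<' (not '<=') so that equal-size cliques are
        # still explored and the lexicographic tie-break is honoured
        potential = len(clique) + bitcount(P | D)
        if count_bonds:
            # bonds in a connected induced molecular subgraph exceed the
            # atom count by at most the (small) cycle rank
            if potential * 2 + 4 < best_atoms + best_bonds:
                return
        elif potential < best_atoms:
            return
        work = P
        while work:
            u = (work & -work).bit_length() - 1
            work &= work - 1
            P &= ~(1 << u)  # cliques containing u are fully explored below
            added_bonds = bitcount(cadj[u] &
                                   _to_bits(clique)) if count_bonds else 0
            newP = (P | D) & compat[u] & ~(1 << u)
            newP_c = newP & cadj[u]
            newP_final = (P & compat[u]) | newP_c
            newD = D & compat[u] & ~cadj[u]
            clique.append(u)
            extend(clique, nbonds + added_bonds, newP_final, newD)
            clique.pop()

    def _to_bits(idxs: list[int]) -> int:
        x = 0
        for v in idxs:
            x |= 1 << v
        return x

    all_later = (1 << nv) - 1
    for s in range(nv):
        # min-vertex seeding: cliques whose smallest vertex is s
        later = all_later & ~((1 << (s + 1)) - 1)
        P0 = cadj[s] & later
        D0 = compat[s] & ~cadj[s] & later
        extend([s], 0, P0, D0)

    return _result(list(best_mapping), best_bonds, molA, molB, semantics)


def _result(mapping, matched_bonds, molA, molB,
            semantics: MatchSemantics) -> MCSResult:
    if semantics.feature_unit == "atoms":
        c = len(mapping)
        a = len(molA) - c
        b = len(molB) - c
    else:
        c = len(mapping) + matched_bonds
        a = len(molA) + len(molA.bonds) - c
        b = len(molB) + len(molB.bonds) - c
    denom = a + b + c
    tan = c / denom if denom else 1.0
    return MCSResult(mapping=list(mapping), c=c, a=a, b=b, tanimoto=tan,
                     matched_bonds=matched_bonds)


# ---------------------------------------------------------------------------
# panel similarity matrix and semantics calibration
# ---------------------------------------------------------------------------

def tanimoto_matrix(panel: list[Molecule],
                    semantics: MatchSemantics = DEFAULT_SEMANTICS
                    ) -> SimilarityMatrix:
    """All-pairs MCS Tanimoto matrix (symmetric, unit diagonal)."""
    ids = [m.identifier for m in panel]
    n = len(panel)
    vals = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            try:
                vals[i, j] = vals[j, i] = mcs(panel[i], panel[j],
                                              semantics).tanimoto
            except ValueError as exc:
                raise ValueError(
                    f"MCS failed for pair ({ids[i]}, {ids[j]}): {exc}"
                ) from exc
    return SimilarityMatrix(identifiers=ids, values=vals)


@dataclass
class CalibrationResult:
    semantics: MatchSemantics
    residuals: dict[tuple[str, str], float]
    max_abs_deviation: float
    grid: dict[MatchSemantics, float]


def calibrate_semantics(panel: list[Molecule],
                        printed_pairs: list[tuple[tuple[str, str], float]]
                        ) -> CalibrationResult:
    """Pick the semantics variant that best reproduces printed coefficients.

    Grid-searches SEMANTICS_GRID and returns the variant minimizing the
    maximum absolute deviation from the printed reference values; ties go
    to the earlier grid entry (atoms before atoms+bonds, charge-blind
    before charge-sensitive, exact before any).
    """
    if not printed_pairs:
        raise ValueError("calibration requires at least one printed pair")
    by_id = {m.identifier: m for m in panel}
    for (ida, idb), _ in printed_pairs:
        if ida not in by_id or idb not in by_id:
            raise KeyError(f"unknown identifier in printed pair ({ida}, {idb})")
    grid_dev: dict[MatchSemantics, float] = {}
    grid_res: dict[MatchSemantics, dict] = {}
    for sem in SEMANTICS_GRID:
        res = {}
        for (ida, idb), ref in printed_pairs:
            t = mcs(by_id[ida], by_id[idb], sem).tanimoto
            res[(ida, idb)] = t - ref
        grid_dev[sem] = max(abs(v) for v in res.values())
        grid_res[sem] = res
    best = min(SEMANTICS_GRID, key=lambda s: grid_dev[s])
    return CalibrationResult(semantics=best, residuals=grid_res[best],
                             max_abs_deviation=grid_dev[best], grid=grid_dev)
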