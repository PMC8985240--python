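"""Exact MCS search and Tanimoto similarity."""

import numpy as np
import pytest

from brushscreen import (MatchSemantics, calibrate_semantics, mcs,
                         parse_smiles, tanimoto_matrix,
                         PRINTED_TANIMOTO_REFERENCES)
from brushscreen.mcs import SEMANTICS_GRID

from conftest import CALIBRATED, brute_force_mcs_size


def mol(smiles, name="m"):
    return parse_smiles(smiles, name)


class TestBasics:
    def test_self_similarity(self):
        g = mol("OCC(O)CO", "Gly")
        r = mcs(g, g)
        assert r.c == len(g) and r.a == r.b == 0
        assert r.tanimoto == 1.0

    def test_disjoint_elements(self):
        r = mcs(mol("C"), mol("O"))
        assert r.c == 0 and r.tanimoto == 0.0

    def test_ethane_propane_atoms_unit(self):
        r = mcs(mol("CC"), mol("CCC"))
        assert (r.c, r.a, r.b) == (2, 0, 1)
        assert r.tanimoto == pytest.approx(2 / 3)

    def test_ethane_propane_atoms_plus_bonds(self):
        r = mcs(mol("CC"), mol("CCC"),
                MatchSemantics(feature_unit="atoms+bonds"))
        # shared: 2 atoms + 1 bond; sizes 3 and 5
        assert (r.c, r.a, r.b) == (3, 0, 2)
        assert r.tanimoto == pytest.approx(3 / 5)

    def test_size_guard(self):
        big = mol("C" * 41, "chain41")
        with pytest.raises(ValueError, match="too large"):
            mcs(big, big)

    def test_deterministic_mapping(self):
        a, b = mol("C=CC(N)=O", "AA"), mol("C=CC(=O)N(C)C", "DMA")
        r1, r2 = mcs(a, b, CALIBRATED), mcs(a, b, CALIBRATED)
        assert r1.mapping == r2.mapping

    def test_mapping_is_valid_common_subgraph(self):
        a = mol("C=C(C)C(=O)NCC(C)O", "HPMA")
        b = mol("C=C(C)C(=O)NCCO", "HEMA")
        r = mcs(a, b, CALIBRATED)
        ai = [p for p, _ in r.mapping]
        bi = [q for _, q in r.mapping]
        assert len(set(ai)) == len(ai) and len(set(bi)) == len(bi)
        lookup = dict(r.mapping)
        for (i, j) in r.mapping:
            assert a.atoms[i].element == b.atoms[j].element
        for i in ai:
            for k in ai:
                if i < k:
                    ea, eb = a.bond_between(i, k), \
                        b.bond_between(lookup[i], lookup[k])
                    assert (ea is None) == (eb is None)  # induced


class TestMatrixProperties:
    def test_symmetry_unit_diagonal_bounds(self, panel_similarity):
        v = panel_similarity.values
        assert np.allclose(v, v.T)
        assert np.allclose(np.diag(v), 1.0)
        assert ((v >= 0) & (v <= 1)).all()

    def test_panel_matrix_shape(self, panel_similarity):
        assert v_shape(panel_similarity) == (14, 14)
        assert len(panel_similarity.to_long()) == 91

    def test_hpma_hema_is_the_top_pair(self, panel_similarity):
        v = panel_similarity.values.copy()
        np.fill_diagonal(v, 0)
        i, j = np.unravel_index(np.argmax(v), v.shape)
        pair = {panel_similarity.identifiers[i],
                panel_similarity.identifiers[j]}
        assert pair == {"HPMA", "HEMA"}

    def test_single_molecule_panel(self):
        m = tanimoto_matrix([mol("CCO", "one")])
        assert m.values.shape == (1, 1) and m.values[0, 0] == 1.0

    def test_tanimoto_one_implies_isomorphic(self):
        a = mol("OCC(O)CO", "g1")
        b = mol("C(CO)(O)CO", "g2")
        r = mcs(a, b)
        assert r.tanimoto == 1.0
        assert brute_force_mcs_size(a, b, CALIBRATED) == len(a)


def v_shape(sim):
    return sim.values.shape


class TestOracleEquivalence:
    def test_backtracking_equals_exhaustive_enumeration(self):
        """Seeded random pairs (<=10 heavy atoms): the clique search must
        find exactly the brute-force maximum size (the full 200-pair run
        lives in the acceptance suite)."""
        from brushscreen import SyntheticMoleculeSpec, generate_molecules
        mols = generate_molecules(SyntheticMoleculeSpec(
            seed=42, n_molecules=40, heavy_atom_range=(3, 10)))
        rng = np.random.default_rng(42)
        sems = [CALIBRATED, MatchSemantics(bond_order="any")]
        for k in range(80):
            a, b = rng.choice(len(mols), size=2, replace=False)
            sem = sems[k % 2]
            got = len(mcs(mols[a], mols[b], sem).mapping)
            want = brute_force_mcs_size(mols[a], mols[b], sem)
            assert got == want, (mols[a].source_smiles,
                                 mols[b].source_smiles, sem)

    def test_monotone_under_terminal_deletion(self):
        from brushscreen import (SyntheticMoleculeSpec, generate_molecules,
                                 perturb)
        mols = generate_molecules(SyntheticMoleculeSpec(
            seed=5, n_molecules=15, heavy_atom_range=(4, 10)))
        ref = mols[0]
        for m in mols[1:]:
            try:
                smaller = perturb(m, "delete_terminal_atom")
            except ValueError:
                continue
            assert len(mcs(smaller, ref).mapping) <= \
                len(mcs(m, ref).mapping)


class TestCalibration:
    def test_returns_single_semantics_with_residuals(self, panel_mols):
        cal = calibrate_semantics(panel_mols,
                                  list(PRINTED_TANIMOTO_REFERENCES.items()))
        assert cal.semantics in SEMANTICS_GRID
        assert set(cal.residuals) == set(PRINTED_TANIMOTO_REFERENCES)
        assert cal.max_abs_deviation == pytest.approx(
            max(abs(v) for v in cal.residuals.values()))

    def test_selected_variant_is_exact_atom_charge_blind(self, panel_mols):
        cal = calibrate_semantics(panel_mols,
                                  list(PRINTED_TANIMOTO_REFERENCES.items()))
        assert cal.semantics == CALIBRATED

    def test_empty_reference_set_raises(self, panel_mols):
        with pytest.raises(ValueError):
            calibrate_semantics(panel_mols, [])

    def test_tie_break_prefers_earlier_grid_entry(self, panel_mols):
        # a single reference that several variants match exactly
        cal = calibrate_semantics(panel_mols, [(("OZ", "OZ"), 1.0)])
        assert cal.semantics == SEMANTICS_GRID[0]
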