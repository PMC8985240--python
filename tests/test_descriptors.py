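"""Descriptor vector, contribution tables and rule filters."""

import numpy as np
import pytest

from brushscreen import compute_descriptors, descriptor_table, parse_smiles
from brushscreen.descriptors import (CONSTANTS, DescriptorError,
                                     bioavailability_score, count_hba,
                                     count_hbd, esol_logs, evaluate_rules,
                                     fraction_csp3, molecular_weight,
                                     rotatable_bonds, tpsa, wlogp,
                                     molar_refractivity, DescriptorVector)


def mol(smiles, name="m"):
    return parse_smiles(smiles, name)


class TestSimpleDescriptors:
    @pytest.mark.parametrize("smiles,mw", [
        ("OCC(O)CO", 92.09), ("O", 18.02), ("C=CC(N)=O", 71.08)])
    def test_molecular_weight(self, smiles, mw):
        assert molecular_weight(mol(smiles)) == pytest.approx(mw, abs=0.01)

    @pytest.mark.parametrize("smiles,f", [
        ("CC", 1.0), ("c1ccccc1", 0.0), ("OCC(O)CO", 1.0)])
    def test_fraction_csp3(self, smiles, f):
        assert fraction_csp3(mol(smiles)) == f

    def test_fraction_csp3_needs_carbon(self):
        with pytest.raises(DescriptorError):
            fraction_csp3(mol("O", "water"))

    @pytest.mark.parametrize("smiles,hba,hbd", [
        ("OCC(O)CO", 3, 3),
        ("c1ccccc1", 0, 0),
        ("C=CC(N)=O", 1, 1),  # carbonyl O accepts; amide N only donates
    ])
    def test_hbond_counts(self, smiles, hba, hbd):
        m = mol(smiles)
        assert count_hba(m) == hba
        assert count_hbd(m) == hbd

    @pytest.mark.parametrize("smiles,rb", [
        ("CC", 0), ("CCCC", 1), ("C=CC(N)=O", 1)])
    def test_rotatable_bonds(self, smiles, rb):
        assert rotatable_bonds(mol(smiles)) == rb


class TestGroupContributions:
    @pytest.mark.parametrize("smiles,value", [
        ("c1ccccc1", 0.0), ("CCO", 20.23), ("OCC(O)CO", 60.69)])
    def test_tpsa(self, smiles, value):
        assert tpsa(mol(smiles)) == pytest.approx(value, abs=0.01)

    def test_wlogp_methane_is_single_type_contribution(self):
        c = CONSTANTS["crippen"]
        expected = c["C1"][0] + 4 * c["H1"][0]
        assert wlogp(mol("C")) == pytest.approx(expected, abs=1e-6)

    def test_wlogp_ch2_increment_constant(self):
        c = CONSTANTS["crippen"]
        inc = wlogp(mol("CCC")) - wlogp(mol("CC"))
        assert inc == pytest.approx(c["C1"][0] + 2 * c["H1"][0], abs=1e-6)

    def test_atom_order_invariance(self):
        assert wlogp(mol("OCC(O)CO")) == wlogp(mol("C(CO)(O)CO"))
        assert molar_refractivity(mol("OCC(O)CO")) == \
            molar_refractivity(mol("C(CO)(O)CO"))

    def test_additivity_over_cc_bridge(self):
        # joining two methyl carbons with a C-C bond removes exactly one
        # hydrogen contribution per side; TPSA is exactly additive
        c = CONSTANTS["crippen"]
        a, b, bridged = mol("CCO"), mol("CC(N)=O"), mol("OCCCC(N)=O")
        assert tpsa(bridged) == pytest.approx(tpsa(a) + tpsa(b), abs=1e-9)
        for fn, col in ((wlogp, 0), (molar_refractivity, 1)):
            assert fn(bridged) == pytest.approx(
                fn(a) + fn(b) - 2 * c["H1"][col], abs=1e-6)

    def test_untypable_environment_raises(self):
        with pytest.raises(DescriptorError, match="TPSA"):
            tpsa(mol("CP", "methylphosphine"))

    def test_deterministic(self):
        m = mol("CC(=O)NC1C(O)CC(O)(C(=O)O)OC1C(O)C(O)CO", "SA")
        assert wlogp(m) == wlogp(m)
        assert tpsa(m) == tpsa(m)


class TestEsol:
    def test_zero_features_return_intercept(self):
        d = DescriptorVector(identifier="x", molecular_weight=0,
                             heavy_atoms=0, fraction_csp3=0, hba=0, hbd=0,
                             rotatable_bonds=0, tpsa=0, wlogp=0,
                             molar_refractivity=0, esol_logs=0)
        assert esol_logs(mol("C"), d) == CONSTANTS["esol"]["intercept"]

    def test_monotone_decreasing_in_wlogp(self):
        assert CONSTANTS["esol"]["wlogp"] < 0

    def test_glycerol_more_soluble_than_benzene(self):
        assert esol_logs(mol("OCC(O)CO")) > esol_logs(mol("c1ccccc1"))


class TestRules:
    def test_glycerol_passes_lipinski_cleanly(self):
        d = compute_descriptors(mol("OCC(O)CO", "Gly"))
        lip = [r for r in evaluate_rules(d) if r.rule_name == "Lipinski"][0]
        assert lip.passes and lip.violations == []

    def test_all_thresholds_crossed(self):
        d = DescriptorVector(identifier="x", molecular_weight=600,
                             heavy_atoms=45, fraction_csp3=0.5, hba=11,
                             hbd=6, rotatable_bonds=5, tpsa=100, wlogp=6,
                             molar_refractivity=100, esol_logs=-5)
        lip = [r for r in evaluate_rules(d) if r.rule_name == "Lipinski"][0]
        assert not lip.passes and len(lip.violations) == 4

    def test_veber_fails_both_conditions(self):
        d = DescriptorVector(identifier="x", molecular_weight=300,
                             heavy_atoms=20, fraction_csp3=0.5, hba=5,
                             hbd=2, rotatable_bonds=11, tpsa=150, wlogp=2,
                             molar_refractivity=80, esol_logs=-3)
        veber = [r for r in evaluate_rules(d) if r.rule_name == "Veber"][0]
        assert not veber.passes and len(veber.violations) == 2

    def test_bioavailability_scores(self):
        gly = mol("OCC(O)CO", "Gly")
        assert bioavailability_score(compute_descriptors(gly), gly) == 0.55
        cbma = mol("C=C(C)C(=O)OCC[N+](C)(C)CCC(=O)[O-]", "CBMA")
        assert bioavailability_score(compute_descriptors(cbma), cbma) == 0.85


class TestTable:
    def test_panel_shape_and_order(self, panel_mols, panel_descriptors):
        assert panel_descriptors.shape == (14, 10)
        assert list(panel_descriptors.index) == \
            [m.identifier for m in panel_mols]

    def test_empty_panel(self):
        df = descriptor_table([])
        assert len(df) == 0
        assert list(df.columns) == list(DescriptorVector.FIELDS)

    def test_duplicates_give_identical_rows(self):
        g = mol("OCC(O)CO", "Gly")
        df = descriptor_table([g, g])
        assert (df.iloc[0] == df.iloc[1]).all()

    def test_failure_names_molecule(self):
        with pytest.raises(DescriptorError, match="weird"):
            descriptor_table([mol("CP", "weird")])

    def test_sa_is_the_structural_outlier(self, panel_descriptors):
        assert panel_descriptors["tpsa"].idxmax() == "SA"
        assert panel_descriptors["heavy_atoms"].idxmax() == "SA"

    def test_descriptors_bit_identical_across_runs(self, panel_mols):
        a = descriptor_table(panel_mols).to_csv()
        b = descriptor_table(panel_mols).to_csv()
        assert a == b
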