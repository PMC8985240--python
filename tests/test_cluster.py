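"""Standardization, distances, UPGMA, tree queries and Newick export."""

import numpy as np
import pandas as pd
import pytest

from brushscreen import (agglomerate, clustroid, cophenetic_matrix,
                         euclidean_distances, heatmap_order, newick_export,
                         standardize)
from brushscreen.cluster import ClusterTree, DistanceMatrix

from conftest import naive_upgma, random_distance_matrix


def dm(ids, values):
    return DistanceMatrix(identifiers=ids, values=np.array(values, float))


class TestStandardize:
    def test_zscore_closed_form(self):
        t = pd.DataFrame({"x": [1.0, 2.0, 3.0]}, index=list("abc"))
        z = standardize(t)["x"].to_numpy()
        assert z == pytest.approx([-1.224745, 0.0, 1.224745], abs=1e-6)

    def test_constant_column_dropped_with_warning(self):
        t = pd.DataFrame({"x": [1.0, 2.0, 3.0], "k": [5.0, 5.0, 5.0]})
        with pytest.warns(UserWarning, match="constant"):
            z = standardize(t)
        assert list(z.columns) == ["x"]

    def test_idempotent(self):
        t = pd.DataFrame({"x": [1.0, 2.0, 3.0, 7.0]})
        once = standardize(t)
        twice = standardize(once)
        assert np.allclose(once.to_numpy(), twice.to_numpy())

    def test_single_row_errors(self):
        with pytest.raises(ValueError):
            standardize(pd.DataFrame({"x": [1.0]}))


class TestDistances:
    def test_three_four_five(self):
        t = pd.DataFrame([[0.0, 0.0], [3.0, 4.0]], index=["a", "b"])
        assert euclidean_distances(t).values[0, 1] == pytest.approx(5.0)

    def test_identical_rows_zero(self):
        t = pd.DataFrame([[1.0, 2.0], [1.0, 2.0]], index=["a", "b"])
        assert euclidean_distances(t).values[0, 1] == 0.0

    def test_matches_elementwise_recomputation(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=(5, 3))
        t = pd.DataFrame(x, index=list("abcde"))
        d = euclidean_distances(t).values
        for i in range(5):
            for j in range(5):
                assert d[i, j] == pytest.approx(
                    np.sqrt(((x[i] - x[j]) ** 2).sum()), abs=1e-12)

    def test_missing_value_names_position(self):
        t = pd.DataFrame({"x": [1.0, np.nan]}, index=["a", "b"])
        with pytest.raises(ValueError, match="'b'"):
            euclidean_distances(t)


class TestAgglomerate:
    def test_two_leaves(self):
        tree = agglomerate(dm(["a", "b"], [[0, 3], [3, 0]]))
        assert tree.merges == [(0, 1, 3.0, 2)]
        assert tree.are_siblings("a", "b")

    def test_three_leaves_average_linkage(self):
        tree = agglomerate(dm(["a", "b", "c"],
                              [[0, 1, 4], [1, 0, 4], [4, 4, 0]]))
        assert tree.merges[0] == (0, 1, 1.0, 3)
        left, right, h, nid = tree.merges[1]
        assert h == pytest.approx(4.0) and nid == 4

    def test_matches_naive_oracle_on_random_matrices(self):
        """100 random matrices (n <= 8): merge sequence and heights equal
        an O(n^3) recomputation from the base matrix."""
        rng = np.random.default_rng(11)
        for _ in range(100):
            n = int(rng.integers(2, 9))
            d = random_distance_matrix(rng, n)
            ids = [f"x{i}" for i in range(n)]
            tree = agglomerate(dm(ids, d))
            expect = naive_upgma(ids, d)
            assert len(tree.merges) == len(expect)
            for got, want in zip(tree.merges, expect):
                assert got[:2] == want[:2]
                assert got[2] == pytest.approx(want[2], abs=1e-9)

    def test_matches_scipy_heights(self):
        from scipy.cluster.hierarchy import average
        from scipy.spatial.distance import squareform
        rng = np.random.default_rng(23)
        d = random_distance_matrix(rng, 7)
        tree = agglomerate(dm([f"x{i}" for i in range(7)], d))
        z = average(squareform(d))
        assert np.allclose(sorted(m[2] for m in tree.merges),
                           sorted(z[:, 2]))

    def test_permutation_invariance(self):
        rng = np.random.default_rng(7)
        d = random_distance_matrix(rng, 6)
        ids = [f"m{i}" for i in range(6)]
        tree = agglomerate(dm(ids, d))
        perm = [3, 1, 5, 0, 4, 2]
        dp = d[np.ix_(perm, perm)]
        tree2 = agglomerate(dm([ids[p] for p in perm], dp))
        coph1 = cophenetic_matrix(tree).to_dataframe().loc[ids, ids]
        coph2 = cophenetic_matrix(tree2).to_dataframe().loc[ids, ids]
        assert np.allclose(coph1.to_numpy(), coph2.to_numpy())

    def test_ultrametric_inequality(self):
        rng = np.random.default_rng(19)
        d = random_distance_matrix(rng, 8)
        tree = agglomerate(dm([f"x{i}" for i in range(8)], d))
        c = cophenetic_matrix(tree).values
        assert np.allclose(c, c.T) and np.allclose(np.diag(c), 0)
        n = len(c)
        for i in range(n):
            for j in range(n):
                for k in range(n):
                    assert c[i, j] <= max(c[i, k], c[k, j]) + 1e-9

    def test_monotone_heights_on_panel(self, panel_descriptors):
        tree = agglomerate(euclidean_distances(standardize(panel_descriptors)))
        assert tree.monotone_heights()

    def test_panel_top_split_isolates_sialic_acid(self, panel_descriptors):
        tree = agglomerate(euclidean_distances(standardize(panel_descriptors)))
        small, big = sorted(tree.top_split(), key=len)
        assert small == {"SA"} and len(big) == 13


class TestClustroid:
    def test_singleton(self):
        d = dm(["a"], [[0.0]])
        assert clustroid(d, {"a"}) == "a"

    def test_collinear_points_pick_middle(self):
        d = dm(["p0", "p1", "p5"],
               [[0, 1, 5], [1, 0, 4], [5, 4, 0]])
        assert clustroid(d, {"p0", "p1", "p5"}) == "p1"

    def test_tie_breaks_lexicographically(self):
        d = dm(["b", "a"], [[0, 2], [2, 0]])
        assert clustroid(d, {"a", "b"}) == "a"

    def test_empty_set_errors(self):
        with pytest.raises(ValueError):
            clustroid(dm(["a"], [[0.0]]), set())


class TestNewickAndOrder:
    def test_two_leaf_format(self):
        tree = ClusterTree(leaves=["A", "B"], merges=[(0, 1, 2.0, 2)])
        assert newick_export(tree) == "(A:2,B:2);"

    def test_round_trip_topology_with_dendropy(self, panel_descriptors):
        dendropy = pytest.importorskip("dendropy")
        tree = agglomerate(euclidean_distances(standardize(panel_descriptors)))
        nwk = newick_export(tree)
        parsed = dendropy.Tree.get(data=nwk, schema="newick")
        assert {t.label for t in parsed.taxon_namespace} == set(tree.leaves)
        # sibling pairs survive serialization
        for a, b in [("HPMA", "HEMA"), ("SBMA", "MPC")]:
            na = parsed.find_node_with_taxon_label(a)
            nb = parsed.find_node_with_taxon_label(b)
            assert na.parent_node is nb.parent_node
            assert tree.are_siblings(a, b)

    def test_heatmap_order_is_leaf_permutation(self, panel_descriptors):
        tree = agglomerate(euclidean_distances(standardize(panel_descriptors)))
        order = heatmap_order(tree)
        assert sorted(order) == sorted(tree.leaves)

    def test_unknown_identifier_errors(self):
        tree = ClusterTree(leaves=["A", "B"], merges=[(0, 1, 2.0, 2)])
        with pytest.raises(KeyError):
            tree.are_siblings("A", "Z")
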