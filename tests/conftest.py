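"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import itertools

import networkx as nx
import numpy as np
import pytest

from brushscreen import (MatchSemantics, descriptor_table, load_panel,
                         tanimoto_matrix)

CALIBRATED = MatchSemantics(feature_unit="atoms", charge_sensitive=False,
                            bond_order="exact")


@pytest.fixture(scope="session")
def panel():
    return load_panel()


@pytest.fixture(scope="session")
def panel_mols(panel):
    return panel.molecules()


@pytest.fixture(scope="session")
def panel_by_id(panel_mols):
    return {m.identifier: m for m in panel_mols}


@pytest.fixture(scope="session")
def panel_descriptors(panel_mols):
    return descriptor_table(panel_mols)


@pytest.fixture(scope="session")
def panel_similarity(panel_mols):
    """Full 14x14 MCS-Tanimoto matrix under the calibrated semantics."""
    return tanimoto_matrix(panel_mols, CALIBRATED)


# ---------------------------------------------------------------------------
# brute-force MCS oracle: exhaustive enumeration of connected induced
# common subgraphs, checked with networkx's VF2 matcher (a code path
# completely independent of the package's clique search)
# ---------------------------------------------------------------------------

def _to_graph(mol, semantics: MatchSemantics) -> nx.Graph:
    g = nx.Graph()
    for a in mol.atoms:
        g.add_node(a.index, element=a.element,
                   charge=a.formal_charge if semantics.charge_sensitive else 0)
    for b in mol.bonds:
        g.add_edge(b.i, b.j,
                   order=b.kek_order if semantics.bond_order == "exact" else 0)
    return g


def brute_force_mcs_size(molA, molB, semantics: MatchSemantics) -> int:
    """Size (atoms) of the largest connected induced common subgraph,
    by enumerating connected atom subsets of the smaller molecule."""
    if len(molB) < len(molA):
        molA, molB = molB, molA
    gA = _to_graph(molA, semantics)
    gB = _to_graph(molB, semantics)
    nm = nx.algorithms.isomorphism.categorical_node_match(
        ["element", "charge"], ["", 0])
    em = nx.algorithms.isomorphism.categorical_edge_match("order", 0)
    nodes = list(gA.nodes)
    for size in range(len(nodes), 0, -1):
        for subset in itertools.combinations(nodes, size):
            sub = gA.subgraph(subset)
            if not nx.is_connected(sub):
                continue
            gm = nx.algorithms.isomorphism.GraphMatcher(
                gB, sub, node_match=nm, edge_match=em)
            if gm.subgraph_is_isomorphic():
                return size
    return 0


# ---------------------------------------------------------------------------
# naive O(n^3) group-average clustering oracle
# ---------------------------------------------------------------------------

def naive_upgma(ids: list[str], d: np.ndarray):
    """Merge list [(left, right, height, new_id)] recomputing every
    cluster-pair average from the base matrix at each step."""
    clusters: dict[int, list[int]] = {i: [i] for i in range(len(ids))}
    merges = []
    nxt = len(ids)
    while len(clusters) > 1:
        best = None
        for i, j in itertools.combinations(sorted(clusters), 2):
            avg = np.mean([d[p, q] for p in clusters[i] for q in clusters[j]])
            key = (avg, i, j)
            if best is None or key < best:
                best = key
        avg, i, j = best
        merges.append((i, j, float(avg), nxt))
        clusters[nxt] = clusters.pop(i) + clusters.pop(j)
        nxt += 1
    return merges


def random_distance_matrix(rng: np.random.Generator, n: int) -> np.ndarray:
    m = rng.uniform(0.1, 10.0, size=(n, n))
    m = (m + m.T) / 2
    np.fill_diagonal(m, 0.0)
    return m
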