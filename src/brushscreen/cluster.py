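"""Agglomerative (group-average/UPGMA) clustering of descriptor tables.

The pipeline mirrors a classical pre-decided configuration: z-score
standardization of the descriptor columns (optional), Euclidean
distances, group-average linkage, and clustroid selection by minimum
sum of distances.  Every tie is broken deterministically (smallest node
index pair / lexicographically smallest identifier), so the tree is
bit-reproducible and invariant to input row order up to leaf labels.

Node numbering: leaves are 0..n-1 in input order; internal nodes are
numbered n, n+1, ... in merge order.  Clade numbering in drawings is a
presentation artifact; only co-membership queries are meaningful.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

__all__ = [
    "DistanceMatrix",
    "ClusterTree",
    "standardize",
    "euclidean_distances",
    "agglomerate",
    "clustroid",
    "newick_export",
    "heatmap_order",
    "cophenetic_matrix",
]


@dataclass
class DistanceMatrix:
    identifiers: list[str]
    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("distance matrix must be square")
        if v.shape[0] != len(self.identifiers):
            raise ValueError("identifier/matrix size mismatch")
        if not np.allclose(v, v.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(v), 0):
            raise ValueError("distance matrix must have zero diagonal")
        if (v < 0).any():
            raise ValueError("distances must be non-negative")
        self.values = v

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.identifiers,
                            columns=self.identifiers)


@dataclass
class ClusterTree:
    """Binary merge tree: (left, right, height, new_node_id) per merge."""

    leaves: list[str]
    merges: list[tuple[int, int, float, int]] = field(default_factory=list)

    def __post_init__(self):
        n = len(self.leaves)
        if self.merges and len(self.merges) != n - 1:
            raise ValueError("a binary tree over n leaves needs n-1 merges")

    @property
    def n_leaves(self) -> int:
        return len(self.leaves)

    @property
    def root(self) -> int:
        return self.merges[-1][3]

    def children(self, node: int) -> tuple[int, int] | None:
        for left, right, _, nid in self.merges:
            if nid == node:
                return (left, right)
        return None

    def height(self, node: int) -> float:
        if node < self.n_leaves:
            return 0.0
        for left, right, h, nid in self.merges:
            if nid == node:
                return h
        raise KeyError(f"unknown node {node}")

    def monotone_heights(self) -> bool:
        hs = [m[2] for m in self.merges]
        return all(h2 >= h1 - 1e-12 for h1, h2 in zip(hs, hs[1:]))

    def clade_members(self, node: int) -> set[str]:
        if node < self.n_leaves:
            return {self.leaves[node]}
        ch = self.children(node)
        if ch is None:
            raise KeyError(f"unknown node {node}")
        return self.clade_members(ch[0]) | self.clade_members(ch[1])

    def leaf_index(self, identifier: str) -> int:
        try:
            return self.leaves.index(identifier)
        except ValueError:
            raise KeyError(f"unknown identifier {identifier!r}") from None

    def are_siblings(self, ida: str, idb: str) -> bool:
        """True iff the two leaves share an immediate parent."""
        i, j = self.leaf_index(ida), self.leaf_index(idb)
        return any({left, right} == {i, j} for left, right, _, _ in self.merges)

    def top_split(self) -> tuple[set[str], set[str]]:
        left, right, _, _ = self.merges[-1]
        return self.clade_members(left), self.clade_members(right)


# ---------------------------------------------------------------------------
# table preparation
# ---------------------------------------------------------------------------

def standardize(table: pd.DataFrame) -> pd.DataFrame:
    """Z-score each column (population sd); constant columns are dropped
    with a warning."""
    if len(table) < 2:
        raise ValueError("standardization needs at least two rows")
    out = {}
    for col in table.columns:
        x = table[col].to_numpy(dtype=float)
        sd = x.std()  # population sd (ddof=0)
        if sd == 0:
            warnings.warn(f"dropping constant column {col!r}", stacklevel=2)
            continue
        out[col] = (x - x.mean()) / sd
    return pd.DataFrame(out, index=table.index)


def euclidean_distances(table: pd.DataFrame) -> DistanceMatrix:
    x = table.to_numpy(dtype=float)
    if np.isnan(x).any():
        i, j = np.argwhere(np.isnan(x))[0]
        raise ValueError(
            f"missing value at row {table.index[i]!r}, column {table.columns[j]!r}")
    d = cdist(x, x, metric="euclidean")
    d = (d + d.T) / 2  # enforce exact symmetry
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(identifiers=[str(i) for i in table.index], values=d)


# ---------------------------------------------------------------------------
# group-average agglomeration
# ---------------------------------------------------------------------------

def agglomerate(dist: DistanceMatrix) -> ClusterTree:
    """Group-average (UPGMA) agglomerative clustering.

    At each step the pair of clusters with the smallest average
    cross-pair leaf distance is merged (ties: smallest node-index pair);
    the merge height is that average distance.  For metric inputs the
    merge heights are non-decreasing; a warning is emitted if an
    inversion appears.
    """
    n = len(dist.identifiers)
    if n < 2:
        raise ValueError("clustering needs at least two items")
    tree = ClusterTree(leaves=list(dist.identifiers))
    # active clusters: node id -> (size, {leaf indices})
    active: dict[int, list[int]] = {i: [i] for i in range(n)}
    # pairwise average distances between active clusters
    d = {}
    base = dist.values
    for i in range(n):
        for j in range(i + 1, n):
            d[(i, j)] = base[i, j]
    next_id = n
    last_h = -np.inf
    while len(active) > 1:
        (i, j), h = min(d.items(), key=lambda kv: (kv[1], kv[0]))
        if h < last_h - 1e-12:
            warnings.warn(
                f"height inversion at merge {next_id}: {h} < {last_h}",
                stacklevel=2)
        last_h = h
        members = active[i] + active[j]
        tree.merges.append((i, j, float(h), next_id))
        del active[i], active[j]
        new_d = {}
        for (p, q), v in d.items():
            if i in (p, q) or j in (p, q):
                continue
            new_d[(p, q)] = v
        for k, mk in active.items():
            # unweighted mean over all cross leaf pairs
            s = base[np.ix_(members, mk)].mean()
            new_d[(min(k, next_id), max(k, next_id))] = float(s)
        active[next_id] = members
        d = new_d
        next_id += 1
    return tree


def clustroid(dist: DistanceMatrix, members: set[str]) -> str:
    """Member minimizing the sum of distances to the other members
    (ties: lexicographically smallest identifier)."""
    if not members:
        raise ValueError("clustroid of an empty set is undefined")
    idx = {m: dist.identifiers.index(m) for m in members}
    best = min(sorted(members),
               key=lambda m: (sum(dist.values[idx[m], idx[o]]
                                  for o in members if o != m), m))
    return best


# ---------------------------------------------------------------------------
# serialization and orderings
# ---------------------------------------------------------------------------

def _ordered_children(tree: ClusterTree, node: int) -> tuple[int, int]:
    left, right = tree.children(node)
    kl = min(tree.clade_members(left))
    kr = min(tree.clade_members(right))
    return (left, right) if kl <= kr else (right, left)


def newick_export(tree: ClusterTree) -> str:
    """Newick string; branch length = parent height - child height.

    Heights are used as-is (merge height, not halved), so the distance
    from the root to every leaf equals the root merge height.  Children
    are ordered by their smallest leaf identifier.
    """

    def render(node: int, parent_h: float) -> str:
        bl = parent_h - tree.height(node)
        if node < tree.n_leaves:
            return f"{tree.leaves[node]}:{bl:g}"
        a, b = _ordered_children(tree, node)
        h = tree.height(node)
        inner = f"({render(a, h)},{render(b, h)})"
        return f"{inner}:{bl:g}"

    root = tree.root
    a, b = _ordered_children(tree, root)
    h = tree.height(root)
    return f"({render(a, h)},{render(b, h)});"


def heatmap_order(tree: ClusterTree) -> list[str]:
    """Leaf ordering from a left-to-right traversal, children ordered by
    smallest leaf identifier."""

    out: list[str] = []

    def walk(node: int) -> None:
        if node < tree.n_leaves:
            out.append(tree.leaves[node])
            return
        a, b = _ordered_children(tree, node)
        walk(a)
        walk(b)

    walk(tree.root)
    return out


def cophenetic_matrix(tree: ClusterTree) -> DistanceMatrix:
    """Pairwise merge heights (the ultrametric the tree induces)."""
    n = tree.n_leaves
    vals = np.zeros((n, n))
    member_cache: dict[int, set[int]] = {i: {i} for i in range(n)}
    for left, right, h, nid in tree.merges:
        lm, rm = member_cache[left], member_cache[right]
        for i in lm:
            for j in rm:
                vals[i, j] = vals[j, i] = h
        member_cache[nid] = lm | rm
    return DistanceMatrix(identifiers=list(tree.leaves), values=vals)


def merge_table(tree: ClusterTree) -> pd.DataFrame:
    rows = []
    sizes: dict[int, int] = {i: 1 for i in range(tree.n_leaves)}
    for left, right, h, nid in tree.merges:
        sizes[nid] = sizes[left] + sizes[right]
        rows.append({"left": left, "right": right, "height": h,
                     "new_node": nid, "size": sizes[nid]})
    return pd.DataFrame(rows, columns=["left", "right", "height",
                                       "new_node", "size"])
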