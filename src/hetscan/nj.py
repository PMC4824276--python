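"""Neighbour-joining tree estimation and bipartition extraction.

The Saitou-Nei algorithm with the Q criterion. Ties in Q are broken by the
lexicographically smallest active index pair, which makes the topology a
deterministic function of the input matrix. Negative branch lengths are
retained (no clamping).

Bipartitions (splits) are the unit of node identity across trees: each
internal edge of an unrooted tree cuts the leaf set in two, and a split is
stored canonically as the side not containing a reference leaf (the
lexicographically smallest leaf label of the tree).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

__all__ = ["Tree", "TreeNode", "nj_tree", "canonical_split", "tree_splits"]


@dataclass
class TreeNode:
    name: str | None = None
    length: float = 0.0
    children: list = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children


@dataclass
class Tree:
    """Unrooted tree, stored with an arbitrary top-level multifurcation."""

    root: TreeNode
    leaf_names: list

    def splits(self) -> set:
        """Canonical nontrivial bipartitions (frozensets of leaf labels)."""
        return tree_splits(self.root, set(self.leaf_names))

    def split_lengths(self) -> dict:
        """Canonical split -> branch length of its internal edge."""
        out = {}
        full = set(self.leaf_names)
        ref = min(full)

        def rec(node):
            below = set()
            for ch in node.children:
                sub = rec(ch)
                if 2 <= len(sub) <= len(full) - 2:
                    out[_canon(sub, ref, full)] = ch.length
                below |= sub
            return below if node.children else {node.name}

        rec(self.root)
        return out

    def newick(self, support: dict | None = None, decimals: int = 6) -> str:
        """Newick string; optional split -> support map written as internal
        node labels."""
        full = set(self.leaf_names)
        ref = min(full)

        def fmt_len(x):
            s = f"{x:.{decimals}f}".rstrip("0").rstrip(".")
            return s if s and s != "-" else "0"

        def rec(node):
            if node.is_leaf:
                return _quote(node.name), {node.name}
            parts, below = [], set()
            for ch in node.children:
                s, sub = rec(ch)
                parts.append(s + f":{fmt_len(ch.length)}")
                below |= sub
            label = ""
            if support is not None and 2 <= len(below) <= len(full) - 2:
                val = support.get(_canon(below, ref, full))
                if val is not None:
                    label = f"{val:g}"
            return "(" + ",".join(parts) + ")" + label, below

        s, _ = rec(self.root)
        return s + ";"


def _quote(name: str) -> str:
    if any(c in name for c in "(),:;[] '\t"):
        return "'" + name.replace("'", "''") + "'"
    return name


def _canon(side: set, ref, full: set) -> frozenset:
    return frozenset(side) if ref not in side else frozenset(full - side)


def canonical_split(side, leaf_set) -> frozenset:
    """Orient a bipartition side away from the smallest leaf of the tree."""
    full = set(leaf_set)
    return _canon(set(side), min(full), full)


def tree_splits(root: TreeNode, full: set) -> set:
    ref = min(full)
    out = set()

    def rec(node):
        if node.is_leaf:
            return {node.name}
        below = set()
        for ch in node.children:
            sub = rec(ch)
            if 2 <= len(sub) <= len(full) - 2:
                out.add(_canon(sub, ref, full))
            below |= sub
        return below

    rec(root)
    return out


@njit(cache=False)
def _nj_merges(D):
    """Neighbour-joining merge sequence on a (copied) distance matrix.

    Returns (joins, lengths, trio, trio_lengths): n-3 joins of matrix
    positions (the merged cluster stays at the first position), their child
    branch lengths, and the final three positions with their lengths.
    Ties in Q resolve to the smallest (i, j) position pair.
    """
    n = D.shape[0]
    alive = np.ones(n, dtype=np.bool_)
    joins = np.empty((n - 3, 2), dtype=np.int64)
    lengths = np.empty((n - 3, 2), dtype=np.float64)
    r = np.empty(n, dtype=np.float64)
    m = n
    for step in range(n - 3):
        for i in range(n):
            if alive[i]:
                s = 0.0
                for j in range(n):
                    if alive[j]:
                        s += D[i, j]
                r[i] = s
        best = np.inf
        bi = -1
        bj = -1
        for i in range(n):
            if not alive[i]:
                continue
            for j in range(i + 1, n):
                if not alive[j]:
                    continue
                q = (m - 2) * D[i, j] - r[i] - r[j]
                if q < best:
                    best = q
                    bi = i
                    bj = j
        dij = D[bi, bj]
        li = 0.5 * dij + (r[bi] - r[bj]) / (2.0 * (m - 2))
        lj = dij - li
        joins[step, 0] = bi
        joins[step, 1] = bj
        lengths[step, 0] = li
        lengths[step, 1] = lj
        for k in range(n):
            if alive[k] and k != bi and k != bj:
                dnew = 0.5 * (D[bi, k] + D[bj, k] - dij)
                D[bi, k] = dnew
                D[k, bi] = dnew
        D[bi, bi] = 0.0
        alive[bj] = False
        m -= 1
    trio = np.empty(3, dtype=np.int64)
    t = 0
    for i in range(n):
        if alive[i]:
            trio[t] = i
            t += 1
    a, b, c = trio[0], trio[1], trio[2]
    tl = np.empty(3, dtype=np.float64)
    tl[0] = 0.5 * (D[a, b] + D[a, c] - D[b, c])
    tl[1] = 0.5 * (D[a, b] + D[b, c] - D[a, c])
    tl[2] = 0.5 * (D[a, c] + D[b, c] - D[a, b])
    return joins, lengths, trio, tl


def nj_tree(dm) -> Tree:
    """Neighbour-joining tree from a :class:`~hetscan.distances.DistanceMatrix`
    (or anything with ``ids`` and ``values``)."""
    labels = list(dm.ids)
    n = len(labels)
    if n < 3:
        raise ValueError(f"neighbour joining needs at least 3 samples, got {n}")
    joins, lengths, trio, tl = _nj_merges(np.array(dm.values, dtype=float))
    nodes = [TreeNode(name=l) for l in labels]
    for (bi, bj), (li, lj) in zip(joins, lengths):
        ci, cj = nodes[bi], nodes[bj]
        ci.length, cj.length = float(li), float(lj)
        nodes[bi] = TreeNode(children=[ci, cj])
    for p, l in zip(trio, tl):
        nodes[p].length = float(l)
    root = TreeNode(children=[nodes[p] for p in trio])
    return Tree(root=root, leaf_names=labels)


def nj_split_indices(values: np.ndarray, n: int) -> list:
    """Topology-only NJ: nontrivial splits as canonical index-frozensets
    (side not containing index 0)."""
    if n < 3:
        raise ValueError(f"neighbour joining needs at least 3 samples, got {n}")
    joins, _, _, _ = _nj_merges(np.array(values, dtype=float))
    leafsets = [frozenset((i,)) for i in range(n)]
    out = []
    for bi, bj in joins:
        merged = leafsets[bi] | leafsets[bj]
        leafsets[bi] = merged
        if len(merged) <= n - 2:
            out.append(merged)
    full = frozenset(range(n))
    return [s if 0 not in s else full - s for s in out]


def nj_splits(values: np.ndarray, labels: list) -> set:
    """Canonical label-frozenset splits of the NJ topology."""
    n = len(labels)
    ref = min(labels)
    full = set(labels)
    out = set()
    for s in nj_split_indices(values, n):
        side = {labels[i] for i in s}
        out.add(_canon(side, ref, full))
    return out
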