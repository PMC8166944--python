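"""Synergistic muscle-group extraction by hierarchical clustering.

Pipeline: activation time series are floored and log2-transformed, pairwise
Euclidean distances between muscles are computed across the time axis, the
Ward.D2 agglomerative criterion builds the merge tree, leaves are arranged
by minimal leaf sorting (the smaller-merge-height subtree first at every
internal node), and muscles are sorted into main groups — and, recursively,
subgroups — by the longest branch lengths from the root.  Branch length is
the difference between parent and child merge heights, so the length from
the root down to any subtree telescopes to ``h_root - h_subtree``; groups
separated by the longest branches are the co-activated muscle synergies.

The number of groups is data-driven (whatever the length criterion yields),
never forced.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from .static_optimization import ActivationSeries

__all__ = [
    "SynergyDendrogram",
    "log_activation",
    "distance_matrix",
    "ward2_cluster",
    "sort_leaves_minimal",
    "cut_longest_branches",
    "extract_synergies",
    "to_newick",
]

#: Default activation floor before log2: activations below ~1e-3 are
#: indistinguishable from silent and would otherwise send log2 to -inf.
LOG_FLOOR = 2.0**-10


def log_activation(a: np.ndarray | ActivationSeries, floor: float = LOG_FLOOR) -> np.ndarray:
    """Elementwise ``log2(max(a, floor))`` of an activation matrix."""
    if floor <= 0:
        raise ValueError("floor must be > 0")
    X = a.a if isinstance(a, ActivationSeries) else np.asarray(a, dtype=float)
    return np.log2(np.maximum(X, floor))


def distance_matrix(X: np.ndarray) -> np.ndarray:
    """Pairwise Euclidean distances between rows (muscles) across time."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be 2-D (muscles x time)")
    if np.any(~np.isfinite(X)):
        raise ValueError("X must contain no missing values")
    diff = X[:, None, :] - X[None, :, :]
    return np.sqrt(np.sum(diff * diff, axis=2))


@dataclass
class SynergyDendrogram:
    """Agglomerative merge tree in scipy linkage form.

    ``linkage`` has n-1 rows ``(left, right, height, count)``; node ids
    0..n-1 are leaves, n..2n-2 internal.  ``labels`` are muscle names in
    input order; ``leaf_order`` is populated by minimal leaf sorting.
    """

    linkage: np.ndarray
    labels: list[str]
    leaf_order: list[int] = field(default_factory=list)

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    def node_height(self, node: int) -> float:
        n = self.n_leaves
        return 0.0 if node < n else float(self.linkage[node - n, 2])

    def children(self, node: int) -> tuple[int, int] | None:
        n = self.n_leaves
        if node < n:
            return None
        row = self.linkage[node - n]
        return int(row[0]), int(row[1])

    def leaves_under(self, node: int) -> list[int]:
        out, stack = [], [node]
        while stack:
            v = stack.pop()
            ch = self.children(v)
            if ch is None:
                out.append(v)
            else:
                stack.extend(ch[::-1])
        return out

    @property
    def root(self) -> int:
        return 2 * self.n_leaves - 2


def ward2_cluster(D: np.ndarray, labels: list[str] | None = None) -> SynergyDendrogram:
    """Agglomerative clustering of a Euclidean distance matrix, Ward.D2.

    The Lance–Williams update is applied to squared distances with
    square-root merge heights — the "ward.D2" convention, under which the
    height of merging two singletons at distance d is d itself.
    """
    D = np.asarray(D, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("D must be a square distance matrix")
    if D.shape[0] < 2:
        raise ValueError("need at least 2 observations to cluster")
    Z = linkage(squareform(D, checks=False), method="ward")
    if labels is None:
        labels = [str(i) for i in range(D.shape[0])]
    return SynergyDendrogram(linkage=Z, labels=list(labels))


def _subtree_min_leaf(tree: SynergyDendrogram, node: int, memo: dict) -> int:
    if node in memo:
        return memo[node]
    ch = tree.children(node)
    v = node if ch is None else min(
        _subtree_min_leaf(tree, ch[0], memo), _subtree_min_leaf(tree, ch[1], memo)
    )
    memo[node] = v
    return v


def sort_leaves_minimal(tree: SynergyDendrogram) -> list[int]:
    """Minimal leaf sorting: smaller-merge-height subtree first.

    At every internal node the child subtree formed at the smaller height
    (leaves count as height 0) is placed first; ties are broken by the
    lowest original leaf index, making the order deterministic.  The order
    is stored on the tree and returned.
    """
    memo: dict[int, int] = {}

    def order(node: int) -> list[int]:
        ch = tree.children(node)
        if ch is None:
            return [node]
        ha, hb = tree.node_height(ch[0]), tree.node_height(ch[1])
        first, second = ch
        if hb < ha or (
            hb == ha
            and _subtree_min_leaf(tree, ch[1], memo) < _subtree_min_leaf(tree, ch[0], memo)
        ):
            first, second = ch[1], ch[0]
        return order(first) + order(second)

    tree.leaf_order = order(tree.root)
    return tree.leaf_order


@dataclass
class SynergyGroups:
    """Main-group and subgroup labels per muscle (input order)."""

    main: np.ndarray  # (n,) int labels, 0-based
    sub: np.ndarray  # (n,) int labels, 0-based within the whole set
    group_nodes: list[int]  # dendrogram node ids of the main groups


def _longest_branch_partition(tree: SynergyDendrogram, root: int, rel_tol: float = 1e-9) -> list[int]:
    """Partition the subtree at ``root`` by the longest-branch criterion.

    For every leaf, the longest edge on its path from ``root`` is found
    (branch length = parent height - child height); the leaf's group is
    the subtree hanging below that edge.  Ties within ``rel_tol`` of the
    longest edge resolve to the edge nearest the root, and equal-length
    sibling branches naturally produce sibling groups.  A zero-height
    (degenerate) subtree yields a single group.
    """
    if tree.children(root) is None or tree.node_height(root) <= 0:
        return [root]
    group_of_leaf: dict[int, int] = {}

    def walk(node: int, best_len: float, best_node: int) -> None:
        ch = tree.children(node)
        if ch is None:
            group_of_leaf[node] = best_node
            return
        hp = tree.node_height(node)
        for c in ch:
            blen = hp - tree.node_height(c)
            if blen > best_len * (1 + rel_tol):
                walk(c, blen, c)
            else:
                walk(c, best_len, best_node)

    walk(root, -np.inf, root)
    nodes: list[int] = []
    for leaf in tree.leaves_under(root):
        g = group_of_leaf[leaf]
        if g not in nodes:
            nodes.append(g)
    return nodes


def cut_longest_branches(tree: SynergyDendrogram, level: str = "main") -> SynergyGroups:
    """Sort muscles into groups by the longest lengths from the root.

    ``level="main"`` partitions the full tree; ``level="sub"`` re-applies
    the same criterion inside each main group, so every muscle ends up in
    exactly one main group and one subgroup.
    """
    if level not in ("main", "sub"):
        raise ValueError("level must be 'main' or 'sub'")
    n = tree.n_leaves
    main_nodes = _longest_branch_partition(tree, tree.root)
    main = np.zeros(n, dtype=int)
    for g, node in enumerate(main_nodes):
        for leaf in tree.leaves_under(node):
            main[leaf] = g
    if level == "main":
        return SynergyGroups(main=main, sub=main.copy(), group_nodes=main_nodes)
    sub = np.zeros(n, dtype=int)
    k = 0
    for node in main_nodes:
        for sub_node in _longest_branch_partition(tree, node):
            for leaf in tree.leaves_under(sub_node):
                sub[leaf] = k
            k += 1
    return SynergyGroups(main=main, sub=sub, group_nodes=main_nodes)


def extract_synergies(
    a: np.ndarray | ActivationSeries,
    labels: list[str] | None = None,
    floor: float = LOG_FLOOR,
) -> tuple[SynergyDendrogram, SynergyGroups]:
    """Full pipeline: log2 -> Euclidean -> Ward.D2 -> leaf sort -> groups."""
    if isinstance(a, ActivationSeries):
        labels = labels or a.muscles
    X = log_activation(a, floor=floor)
    D = distance_matrix(X)
    tree = ward2_cluster(D, labels=labels)
    sort_leaves_minimal(tree)
    groups = cut_longest_branches(tree, level="sub")
    return tree, groups


def to_newick(tree: SynergyDendrogram) -> str:
    """Newick text with branch lengths (parent height - child height)."""

    def rec(node: int, parent_h: float) -> str:
        h = tree.node_height(node)
        blen = parent_h - h
        ch = tree.children(node)
        if ch is None:
            return f"{tree.labels[node]}:{blen:.8g}"
        inner = ",".join(rec(c, h) for c in ch)
        return f"({inner}):{blen:.8g}"

    root = tree.root
    h = tree.node_height(root)
    inner = ",".join(rec(c, h) for c in tree.children(root))
    return f"({inner});"
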