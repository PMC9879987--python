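"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's algorithmic code paths: they use only
structural accessors (parents, branch lengths, traversal order) and recompute
every quantity by enumeration or discretization.
"""

from __future__ import annotations

from itertools import product
from typing import Dict, List, Sequence, Tuple

import numpy as np

from virogenescape.phylo import Tree


def _ancestor_chain(node) -> List:
    chain = [node]
    while chain[-1].parent_node is not None:
        chain.append(chain[-1].parent_node)
    return chain


def _node_depths(tree: Tree) -> Dict[int, float]:
    depth = {id(tree.root): 0.0}
    for node in tree.nodes():
        if node is not tree.root:
            depth[id(node)] = depth[id(node.parent_node)] + tree.branch_length(node)
    return depth


def _pairwise_dist(tree: Tree, x, y, depth) -> float:
    anc_x = {id(n): n for n in _ancestor_chain(x)}
    lca = next(n for n in _ancestor_chain(y) if id(n) in anc_x)
    return depth[id(x)] + depth[id(y)] - 2 * depth[id(lca)]


def lca_by_path_intersection(tree: Tree, taxa: Sequence[str]):
    """LCA as the deepest node common to every leaf's root path."""
    depth = _node_depths(tree)
    common = None
    for name in taxa:
        chain = {id(n) for n in _ancestor_chain(tree.leaf(name))}
        common = chain if common is None else (common & chain)
    candidates = [n for n in tree.nodes() if id(n) in common]
    return max(candidates, key=lambda n: depth[id(n)])


def midpoint_radius_by_discretization(tree: Tree, n_grid: int = 1000) -> float:
    """Minimum over all edge points of the maximum point-to-leaf distance.

    Every edge is sampled at ``n_grid + 1`` evenly spaced points; the true
    optimum lies within (max edge length) / (2 * n_grid) of the returned value.
    """
    depth = _node_depths(tree)
    leaves = [tree.leaf(l) for l in tree.leaf_labels]
    below: Dict[int, set] = {}
    for node in tree.postorder():
        if node.is_leaf():
            below[id(node)] = {node.taxon.label}
        else:
            below[id(node)] = set().union(*(below[id(c)] for c in node.child_nodes()))

    best = np.inf
    for child in tree.nodes():
        if child is tree.root:
            continue
        parent = child.parent_node
        L = tree.branch_length(child)
        d_child = {lf.taxon.label: _pairwise_dist(tree, child, lf, depth) for lf in leaves}
        d_parent = {lf.taxon.label: _pairwise_dist(tree, parent, lf, depth) for lf in leaves}
        inside = below[id(child)]
        a = max(d_child[l] for l in inside)
        outside = [l for l in d_parent if l not in inside]
        b = max((d_parent[l] for l in outside), default=-np.inf)
        t = np.linspace(0.0, L, n_grid + 1)
        vals = np.maximum(a + t, b + (L - t)) if outside else a + t
        best = min(best, float(vals.min()))
    return best


def moving_average_smooth(raw: np.ndarray, W: int) -> np.ndarray:
    """Explicit double-loop centered truncated moving average over defined bins."""
    B, C = raw.shape
    left, right = (W - 1) // 2, W // 2
    out = np.full_like(raw, np.nan)
    for i in range(B):
        acc, n = np.zeros(C), 0
        for j in range(max(0, i - left), min(B - 1, i + right) + 1):
            if not np.isnan(raw[j, 0]):
                acc += raw[j]
                n += 1
        if n:
            out[i] = acc / n
    return out


def sankoff_by_enumeration(tree: Tree, leaf_counts: Dict[str, int]) -> float:
    """Minimum total |i - j| change cost over all ancestral assignments."""
    internal = [n for n in tree.nodes() if not n.is_leaf()]
    max_state = max(leaf_counts.values())
    best = np.inf
    for states in product(range(max_state + 1), repeat=len(internal)):
        assign = {id(n): s for n, s in zip(internal, states)}
        for lf in tree.leaf_labels:
            assign[id(tree.leaf(lf))] = leaf_counts[lf]
        cost = sum(
            abs(assign[id(n)] - assign[id(n.parent_node)])
            for n in tree.nodes()
            if n is not tree.root
        )
        best = min(best, cost)
    return float(best)
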