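"""Species-tree handling: Newick I/O, midpoint rooting, LCA and root-path queries.

The tree is the backbone of every downstream analysis: gene-age (phylostratum)
assignment needs last-common-ancestor queries against the rooted topology, and
branch-wise duplication rates need branch lengths.  Trees are stored as thin
wrappers around :class:`dendropy.Tree`, which supplies robust Newick parsing
(quoted labels, ``[...]`` comments, internal node labels) and traversal
machinery; rooting and LCA logic live here so that tie-breaking and the
degree-2 root produced by midpoint rooting follow documented rules.

Conventions
-----------
* Branch lengths are substitutions/site on the edge *above* each node; a
  missing length in the input is read as 0.
* Midpoint rooting places the root at the point halving the longest
  leaf-to-leaf patristic path.  The resulting root has degree 2 and is kept
  (not collapsed), so the depth of a leaf — and hence the number of
  phylostrata on its root path — is well defined.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Sequence, Set

import dendropy

__all__ = ["Tree", "PathStrata", "TreeError", "parse_newick", "write_newick", "midpoint_root"]

_EPS = 1e-12


class TreeError(ValueError):
    """Malformed tree input or an invalid query against a tree."""


class Tree:
    """A rooted (or conventionally seed-rooted) species tree with branch lengths.

    Nodes are :class:`dendropy.Node` objects; leaves carry unique non-empty
    taxon labels.  The wrapper validates invariants on construction: unique
    leaf labels and non-negative branch lengths.
    """

    def __init__(self, dtree: dendropy.Tree):
        dtree.is_rooted = True
        self._dtree = dtree
        self._normalize_and_validate()
        self._leaf_by_label: Dict[str, dendropy.Node] = {
            leaf.taxon.label: leaf for leaf in dtree.leaf_node_iter()
        }
        self._leafset_cache: Dict[int, frozenset] = {}

    # ------------------------------------------------------------------ I/O

    @classmethod
    def from_newick(cls, text: str) -> "Tree":
        """Parse a Newick string (quoted labels and comments tolerated)."""
        if ";" not in text:
            raise TreeError("Newick parse error: missing terminating ';'")
        try:
            dtree = dendropy.Tree.get(
                data=text,
                schema="newick",
                preserve_underscores=True,
                suppress_internal_node_taxa=True,
            )
        except Exception as exc:  # dendropy raises several error classes
            raise TreeError(f"Newick parse error: {exc}") from exc
        return cls(dtree)

    @classmethod
    def from_file(cls, path) -> "Tree":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_newick(fh.read())

    def to_newick(self) -> str:
        out = self._dtree.as_string(
            schema="newick",
            suppress_rooting=True,
            unquoted_underscores=True,
        )
        return out.strip() + "\n"

    def to_file(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(self.to_newick())

    # ------------------------------------------------------- basic structure

    @property
    def root(self) -> dendropy.Node:
        return self._dtree.seed_node

    @property
    def leaf_labels(self) -> List[str]:
        return list(self._leaf_by_label)

    def leaf(self, label: str) -> dendropy.Node:
        try:
            return self._leaf_by_label[label]
        except KeyError:
            raise TreeError(f"unknown taxon name: {label!r}") from None

    def nodes(self) -> List[dendropy.Node]:
        return list(self._dtree.preorder_node_iter())

    def postorder(self) -> List[dendropy.Node]:
        return list(self._dtree.postorder_node_iter())

    def branch_length(self, node: dendropy.Node) -> float:
        return float(node.edge.length or 0.0)

    def parent(self, node: dendropy.Node):
        return node.parent_node

    def n_leaves(self) -> int:
        return len(self._leaf_by_label)

    def label_of(self, node: dendropy.Node) -> str:
        """Stable label: taxon label for leaves, assigned ``nodeNN`` otherwise."""
        if node.taxon is not None:
            return node.taxon.label
        if node.label:
            return node.label
        return self._anon_labels[id(node)]

    def copy(self) -> "Tree":
        return Tree(self._dtree.clone(depth=1))

    # ------------------------------------------------------------- validation

    def _normalize_and_validate(self) -> None:
        labels: Set[str] = set()
        self._anon_labels: Dict[int, str] = {}
        k = 0
        for node in self._dtree.postorder_node_iter():
            if node.edge.length is None:
                node.edge.length = 0.0
            if node.edge.length < 0:
                raise TreeError(
                    f"negative branch length {node.edge.length} above node "
                    f"{node.taxon.label if node.taxon else node.label!r}"
                )
            if node.is_leaf():
                if node.taxon is None or not node.taxon.label:
                    raise TreeError("leaf without a taxon label")
                if node.taxon.label in labels:
                    raise TreeError(f"duplicate leaf label: {node.taxon.label!r}")
                labels.add(node.taxon.label)
            elif node.taxon is None and not node.label:
                self._anon_labels[id(node)] = f"node{k}"
                k += 1
        self._dtree.seed_node.edge.length = 0.0

    # ------------------------------------------------------------- distances

    def leafward_max_dist(self) -> Dict[int, float]:
        """id(node) -> max patristic distance from node down to a descendant leaf."""
        down: Dict[int, float] = {}
        for node in self._dtree.postorder_node_iter():
            if node.is_leaf():
                down[id(node)] = 0.0
            else:
                down[id(node)] = max(
                    down[id(c)] + self.branch_length(c) for c in node.child_nodes()
                )
        return down

    def root_to_leaf_distances(self) -> Dict[str, float]:
        dist: Dict[int, float] = {id(self.root): 0.0}
        out: Dict[str, float] = {}
        for node in self._dtree.preorder_node_iter():
            if node is not self.root:
                dist[id(node)] = dist[id(node.parent_node)] + self.branch_length(node)
            if node.is_leaf():
                out[node.taxon.label] = dist[id(node)]
        return out

    # ------------------------------------------------------------------- LCA

    def leafset(self, node: dendropy.Node) -> frozenset:
        key = id(node)
        if key not in self._leafset_cache:
            for n in self._dtree.postorder_node_iter():
                if id(n) in self._leafset_cache:
                    continue
                if n.is_leaf():
                    self._leafset_cache[id(n)] = frozenset([n.taxon.label])
                else:
                    acc: Set[str] = set()
                    for c in n.child_nodes():
                        acc |= self._leafset_cache[id(c)]
                    self._leafset_cache[id(n)] = frozenset(acc)
        return self._leafset_cache[key]

    def lca(self, taxa: Iterable[str]) -> dendropy.Node:
        """Deepest node whose descendant leaves include every name in *taxa*."""
        names = set(taxa)
        if not names:
            raise TreeError("lca of an empty taxon set is undefined")
        unknown = sorted(n for n in names if n not in self._leaf_by_label)
        if unknown:
            raise TreeError(f"unknown taxon name(s): {', '.join(unknown)}")
        node = self._leaf_by_label[next(iter(names))]
        while not names <= self.leafset(node):
            node = node.parent_node
        return node

    # ------------------------------------------------------------ root paths

    def strata_path(self, focal: str) -> "PathStrata":
        """Ordered ancestors of the focal leaf, from its parent up to the root."""
        leaf = self.leaf(focal)
        nodes: List[dendropy.Node] = []
        node = leaf.parent_node
        while node is not None:
            nodes.append(node)
            node = node.parent_node
        if not nodes:
            raise TreeError("tree has a single node; no root path exists")
        return PathStrata(focal=focal, nodes=nodes)

    # -------------------------------------------------------------- midpoint

    def midpoint_root(self) -> "Tree":
        """Reroot at the midpoint of the longest leaf-to-leaf patristic path.

        The optimal point minimizes the maximum point-to-leaf distance (the
        tree radius, i.e. half the diameter).  Among edges attaining the
        radius, the first in post-order is used; if the optimum falls exactly
        on an existing node the tree is rerooted there, otherwise the edge is
        split by a new degree-2 root node.
        """
        work = self._dtree.clone(depth=1)
        tmp = Tree(work)
        down = tmp.leafward_max_dist()
        if max(down[id(work.seed_node)], 0.0) <= 0.0:
            raise TreeError("midpoint undefined: all branch lengths are zero")
        if tmp.n_leaves() < 2:
            raise TreeError("midpoint rooting needs at least 2 leaves")

        # up[id(v)] = max distance from v's parent to any leaf NOT below v
        up: Dict[int, float] = {}
        for node in work.preorder_node_iter():
            children = node.child_nodes()
            for i, v in enumerate(children):
                sib_max = max(
                    (down[id(w)] + tmp.branch_length(w) for j, w in enumerate(children) if j != i),
                    default=float("-inf"),
                )
                if node is work.seed_node:
                    up[id(v)] = sib_max if sib_max > float("-inf") else 0.0
                else:
                    par_up = up[id(node)] + tmp.branch_length(node)
                    up[id(v)] = max(sib_max, par_up)

        best = None  # (radius, edge child node, t from child)
        for node in work.postorder_node_iter():
            if node is work.seed_node:
                continue
            L = tmp.branch_length(node)
            a, b = down[id(node)], up[id(node)]  # leafward / rootward extremes
            t = min(max((b + L - a) / 2.0, 0.0), L)
            radius = max(a + t, b + (L - t))
            if best is None or radius < best[0] - _EPS:
                best = (radius, node, t)
        assert best is not None
        _, child, t = best
        L = tmp.branch_length(child)

        if t <= _EPS:
            new_root = child
        elif t >= L - _EPS:
            new_root = child.parent_node
        else:
            parent = child.parent_node
            parent.remove_child(child)
            new_root = dendropy.Node()
            parent.add_child(new_root)
            new_root.edge.length = L - t
            new_root.add_child(child)
            child.edge.length = t
        if new_root is not work.seed_node:
            # A previous degree-2 root left behind by rerooting is collapsed
            # (suppress_unifurcations); the new seed keeps two children.
            work.reseed_at(
                new_root,
                update_bipartitions=False,
                collapse_unrooted_basal_bifurcation=False,
                suppress_unifurcations=True,
            )
        return Tree(work)


@dataclass
class PathStrata:
    """The focal leaf's ancestor chain: stratum ``i`` (1-based) is ``nodes[i-1]``."""

    focal: str
    nodes: List[dendropy.Node]
    category_of: Dict[int, int] = field(default_factory=dict)  # id(node) -> category

    def __len__(self) -> int:
        return len(self.nodes)


# Functional aliases matching the operation-style API used across modules.

def parse_newick(text: str) -> Tree:
    return Tree.from_newick(text)


def write_newick(tree: Tree) -> str:
    return tree.to_newick()


def midpoint_root(tree: Tree) -> Tree:
    return tree.midpoint_root()


def lca(tree: Tree, taxa: Iterable[str]) -> dendropy.Node:
    return tree.lca(taxa)


def strata_path(tree: Tree, focal: str) -> PathStrata:
    return tree.strata_path(focal)
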