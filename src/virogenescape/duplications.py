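"""Branch-wise gene-duplication counts from orthogroup copy numbers.

Ancestral copy numbers are reconstructed per orthogroup by linear-cost
Wagner/Sankoff parsimony (states 0..max observed count, transition cost
|i - j|).  A duplication on the branch above node v is a copy-number increase
relative to the parent, ``max(0, n(v) - n(parent))``; decreases are losses
and reported separately.  Per-branch totals are normalized by branch length
and log10-transformed, giving the duplication-rate coloring of the species
tree.  This is a desk-scale stand-in for gene-tree reconciliation: it counts
the minimum number of copy-number gains compatible with the table, so
parallel gains on sister branches can be collapsed onto their parent.

Ties are broken toward the smallest ancestral state (conservative counts,
deterministic output).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Tuple

import numpy as np
import pandas as pd

from .ancestry import OrthogroupTable
from .phylo import Tree, TreeError

__all__ = [
    "CopyNumberMatrix",
    "BranchDuplicationReport",
    "copy_numbers",
    "infer_branch_duplications",
    "normalize_duplications",
]


@dataclass
class CopyNumberMatrix:
    """Orthogroup x taxon matrix of gene copy counts."""

    counts: pd.DataFrame  # index: orthogroup ID, columns: taxa, values: int >= 0

    @property
    def taxa(self) -> List[str]:
        return list(self.counts.columns)


@dataclass
class BranchDuplicationReport:
    """Per-branch duplication/loss totals; one row per non-root node (= the
    branch above it), with rate = dup_count / branch_length and its log10.

    ``rate`` is NaN for zero-length branches; ``log10_rate`` is NaN whenever
    the rate is undefined or zero (flagged, never dropped).
    """

    table: pd.DataFrame  # columns: branch, dup_count, loss_count, branch_length, rate, log10_rate
    total_cost: float

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False, float_format="%.6g")


def copy_numbers(table: OrthogroupTable) -> CopyNumberMatrix:
    """Copy counts per orthogroup/taxon: the length of each cell's gene list."""
    data = {
        og: {t: len(row.get(t, [])) for t in table.taxa}
        for og, row in table.membership.items()
    }
    df = pd.DataFrame.from_dict(data, orient="index", columns=table.taxa).fillna(0)
    return CopyNumberMatrix(counts=df.astype(int))


def _sankoff_states(
    tree: Tree, leaf_counts: Dict[str, int]
) -> Tuple[Dict[int, int], float]:
    """Minimum-change ancestral copy numbers for one orthogroup.

    Returns (id(node) -> state, optimal total cost).  Bottom-up DP over
    states 0..max(count); top-down assignment picks, for each node, the
    smallest state minimizing subtree cost + |state - parent state|.
    """
    max_state = max(leaf_counts.values())
    n_states = max_state + 1
    states = np.arange(n_states)
    trans = np.abs(states[:, None] - states[None, :])  # trans[parent, child]

    cost: Dict[int, np.ndarray] = {}
    for node in tree.postorder():
        if node.is_leaf():
            c = np.full(n_states, np.inf)
            c[leaf_counts[node.taxon.label]] = 0.0
        else:
            c = np.zeros(n_states)
            for child in node.child_nodes():
                c += (trans + cost[id(child)][None, :]).min(axis=1)
        cost[id(node)] = c

    assign: Dict[int, int] = {}
    root = tree.root
    root_cost = cost[id(root)]
    assign[id(root)] = int(np.argmin(root_cost))  # argmin takes the smallest tie
    for node in tree.nodes():
        if node is root:
            continue
        s_parent = assign[id(node.parent_node)]
        assign[id(node)] = int(np.argmin(trans[s_parent] + cost[id(node)]))
    return assign, float(root_cost.min())


def infer_branch_duplications(
    matrix: CopyNumberMatrix, tree: Tree
) -> BranchDuplicationReport:
    """Sum per-branch copy-number gains (duplications) and decreases (losses)
    over all orthogroups under linear-cost parsimony."""
    missing = [t for t in matrix.taxa if t not in set(tree.leaf_labels)]
    if missing:
        raise TreeError(f"copy-number taxa not in the tree: {', '.join(missing)}")
    extra = [t for t in tree.leaf_labels if t not in set(matrix.taxa)]
    if extra:
        raise TreeError(f"tree leaves missing from the copy-number matrix: {', '.join(extra)}")

    branches = [n for n in tree.nodes() if n is not tree.root]
    dup = {id(n): 0 for n in branches}
    loss = {id(n): 0 for n in branches}
    total_cost = 0.0

    for og_id, row in matrix.counts.iterrows():
        leaf_counts = {t: int(row[t]) for t in matrix.taxa}
        if max(leaf_counts.values()) == 0:
            continue
        assign, cost = _sankoff_states(tree, leaf_counts)
        total_cost += cost
        for node in branches:
            delta = assign[id(node)] - assign[id(node.parent_node)]
            if delta > 0:
                dup[id(node)] += delta
            elif delta < 0:
                loss[id(node)] += -delta

    table = pd.DataFrame(
        {
            "branch": [tree.label_of(n) for n in branches],
            "dup_count": [dup[id(n)] for n in branches],
            "loss_count": [loss[id(n)] for n in branches],
            "branch_length": [tree.branch_length(n) for n in branches],
        }
    )
    table["rate"] = np.nan
    table["log10_rate"] = np.nan
    return BranchDuplicationReport(table=table, total_cost=total_cost)


def normalize_duplications(
    report: BranchDuplicationReport, tree: Tree = None
) -> BranchDuplicationReport:
    """Fill duplication rates (count / branch length) and their log10.

    Undefined values (zero-length branch, or zero duplications for the log)
    stay NaN so downstream consumers can flag rather than drop them.
    """
    t = report.table
    with np.errstate(divide="ignore", invalid="ignore"):
        rate = np.where(t["branch_length"] > 0, t["dup_count"] / t["branch_length"], np.nan)
        log10_rate = np.where(
            (t["dup_count"] > 0) & (t["branch_length"] > 0), np.log10(rate), np.nan
        )
    t = t.assign(rate=rate, log10_rate=log10_rate)
    return BranchDuplicationReport(table=t, total_cost=report.total_cost)
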