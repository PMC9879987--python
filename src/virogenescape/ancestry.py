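"""Per-gene ancestry (phylostratum) scoring from orthogroup presence/absence.

Each focal-genome gene is assigned an integer ancestry score: 0 for genes
found only in the focal genome (ORFans), and otherwise the stratum of the
last common ancestor of all taxa carrying a homolog, counted along the focal
leaf's root path.  On the default study-structure tree the scores run from 0
(strain-specific) to 5 (shared with at least one phycodnavirus-like taxon).

Homolog presence is binary per taxon (at least one gene listed in the
orthogroup cell); copy numbers are only used by the duplications module.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set

import pandas as pd

from .phylo import PathStrata, Tree, TreeError

__all__ = [
    "OrthogroupTable",
    "StrataMap",
    "AncestryAssignment",
    "taxa_with_homolog",
    "ancestry_score",
    "score_all",
]


class OrthogroupError(ValueError):
    """Inconsistent orthogroup table (e.g. a gene listed in two orthogroups)."""


@dataclass
class OrthogroupTable:
    """Orthogroup membership: orthogroup ID -> per-taxon gene-ID lists.

    Mirrors the OrthoFinder ``Orthogroups.tsv`` dialect: one row per
    orthogroup, one column per taxon, cells holding comma-separated gene IDs
    (empty cell = no member in that taxon).
    """

    taxa: List[str]
    membership: Dict[str, Dict[str, List[str]]]

    def gene_index(self, focal: str) -> Dict[str, str]:
        """Map each focal-taxon gene ID to its orthogroup; error on conflicts."""
        index: Dict[str, str] = {}
        for og_id, row in self.membership.items():
            for gene in row.get(focal, ()):
                if gene in index and index[gene] != og_id:
                    raise OrthogroupError(
                        f"gene {gene!r} listed in orthogroups {index[gene]!r} and {og_id!r}"
                    )
                index[gene] = og_id
        return index

    def presence(self, og_id: str) -> Set[str]:
        """Taxa with at least one gene in the orthogroup."""
        return {t for t, genes in self.membership[og_id].items() if genes}

    # ----------------------------------------------------------------- I/O

    @classmethod
    def from_tsv(cls, path) -> "OrthogroupTable":
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
        if df.columns[0] != "Orthogroup":
            raise OrthogroupError(
                f"orthogroup table {path}: first column must be 'Orthogroup', "
                f"got {df.columns[0]!r}"
            )
        taxa = list(df.columns[1:])
        if len(set(taxa)) != len(taxa):
            raise OrthogroupError(f"orthogroup table {path}: duplicate taxon columns")
        membership: Dict[str, Dict[str, List[str]]] = {}
        for _, row in df.iterrows():
            og = row["Orthogroup"]
            if og in membership:
                raise OrthogroupError(f"duplicate orthogroup ID {og!r}")
            membership[og] = {
                t: [g.strip() for g in row[t].split(",") if g.strip()] for t in taxa
            }
        return cls(taxa=taxa, membership=membership)

    def to_tsv(self, path) -> None:
        rows = []
        for og_id, row in self.membership.items():
            rec = {"Orthogroup": og_id}
            for t in self.taxa:
                rec[t] = ", ".join(row.get(t, []))
            rows.append(rec)
        pd.DataFrame(rows, columns=["Orthogroup", *self.taxa]).to_csv(
            path, sep="\t", index=False
        )


@dataclass
class StrataMap:
    """Mapping from focal root-path nodes to integer ancestry categories.

    ``category_of`` is keyed by ``id(node)``; categories must be monotone
    non-decreasing from the shallowest path node to the root and form a
    contiguous range ``1..S`` (category 0 is reserved for focal-only genes).
    """

    category_of: Dict[int, int]
    S: int
    focal_only_category: int = 0

    @classmethod
    def identity(cls, tree: Tree, focal: str) -> "StrataMap":
        """Category i = i-th ancestor of the focal leaf (parent = 1, root = depth)."""
        path = tree.strata_path(focal)
        cats = {id(n): i for i, n in enumerate(path.nodes, start=1)}
        return cls(category_of=cats, S=len(path.nodes))

    @classmethod
    def collapsed(cls, tree: Tree, focal: str, categories: Sequence[int]) -> "StrataMap":
        """Collapse the root path into user-chosen categories.

        ``categories[i]`` is the category of the i-th ancestor (0-based, from
        the focal leaf's parent).  Used when the root path is deeper than the
        desired number of strata, e.g. grouping all within-family nodes.
        """
        path = tree.strata_path(focal)
        if len(categories) != len(path.nodes):
            raise ValueError(
                f"need {len(path.nodes)} categories for the focal root path, "
                f"got {len(categories)}"
            )
        cats = [int(c) for c in categories]
        if any(b < a for a, b in zip(cats, cats[1:])):
            raise ValueError("strata categories must be non-decreasing toward the root")
        if sorted(set(cats)) != list(range(1, max(cats) + 1)):
            raise ValueError("strata categories must form a contiguous range 1..S")
        return cls(
            category_of={id(n): c for n, c in zip(path.nodes, cats)}, S=max(cats)
        )


@dataclass
class AncestryAssignment:
    """Per-gene integer ancestry score for the focal genome."""

    focal: str
    S: int
    score: Dict[str, int] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"gene_id": list(self.score), "ancestry_score": list(self.score.values())}
        )

    def to_tsv(self, path) -> None:
        df = self.to_frame()
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(f"# focal={self.focal}\tS={self.S}\n")
            df.to_csv(fh, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "AncestryAssignment":
        focal, S = "", 0
        with open(path, "r", encoding="utf-8") as fh:
            first = fh.readline()
            if first.startswith("#"):
                meta = dict(tok.split("=", 1) for tok in first[1:].split() if "=" in tok)
                focal, S = meta.get("focal", ""), int(meta.get("S", 0))
            else:
                fh.seek(0)
            df = pd.read_csv(fh, sep="\t", dtype={"gene_id": str})
        scores = dict(zip(df["gene_id"], df["ancestry_score"].astype(int)))
        return cls(focal=focal, S=S or (max(scores.values()) if scores else 0), score=scores)


def taxa_with_homolog(table: OrthogroupTable, gene: str, focal: str) -> Set[str]:
    """Taxa carrying a homolog of a focal gene; ``{focal}`` if the gene is in
    no orthogroup or its orthogroup has members in no other taxon."""
    og_id = table.gene_index(focal).get(gene)
    if og_id is None:
        return {focal}
    return table.presence(og_id) | {focal}


def ancestry_score(tree: Tree, focal: str, present: Set[str], strata: StrataMap) -> int:
    """Score one presence set: 0 if focal-only, else stratum of LCA(present)."""
    if focal not in present:
        raise ValueError(f"focal taxon {focal!r} missing from its own presence set")
    if present == {focal}:
        return strata.focal_only_category
    unknown = sorted(set(present) - set(tree.leaf_labels))
    if unknown:
        raise TreeError(f"presence set names taxa not in the tree: {', '.join(unknown)}")
    node = tree.lca(present)
    if node.is_leaf():  # LCA is the focal leaf itself
        return strata.focal_only_category
    try:
        return strata.category_of[id(node)]
    except KeyError:
        raise ValueError(
            "strata map does not cover the LCA node; it must cover every node "
            "on the focal root path"
        ) from None


def score_all(
    table: OrthogroupTable,
    tree: Tree,
    focal: str,
    strata: StrataMap,
    gene_ids: Optional[Iterable[str]] = None,
) -> AncestryAssignment:
    """Score every focal gene (those in the table, plus any extra IDs given).

    Genes absent from every orthogroup score 0 (ORFan convention).
    """
    index = table.gene_index(focal)
    genes = list(gene_ids) if gene_ids is not None else sorted(index)
    assignment = AncestryAssignment(focal=focal, S=strata.S)
    presence_cache: Dict[str, int] = {}
    for gene in genes:
        og_id = index.get(gene)
        if og_id is None:
            assignment.score[gene] = strata.focal_only_category
            continue
        if og_id not in presence_cache:
            present = table.presence(og_id) | {focal}
            presence_cache[og_id] = ancestry_score(tree, focal, present, strata)
        assignment.score[gene] = presence_cache[og_id]
    return assignment
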