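"""End-to-end orchestration: root -> score -> density -> duplications -> essentiality.

:func:`run_full` reads the four inputs (tree, orthogroups, annotation,
fitness), validates their cross-references up front (aggregating every
problem into one error), runs each analysis stage, and writes TSV/JSON
reports plus a manifest echoing the configuration and seed.  Stages whose
inputs are absent (e.g. no fitness table) are skipped and recorded as such.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np

from . import io as vio
from .ancestry import AncestryAssignment, OrthogroupTable, StrataMap, score_all
from .duplications import copy_numbers, infer_branch_duplications, normalize_duplications
from .essentiality import (
    DEFAULT_TAU,
    classify_essential,
    core_region,
    depth_phenotype_summary,
)
from .genomescape import (
    assign_bins,
    category_fractions,
    position_trend,
    smooth_profile,
)
from .phylo import Tree

__all__ = ["RunConfig", "ValidationError", "run_full"]


class ValidationError(ValueError):
    """Aggregated cross-reference failures across input files."""


@dataclass
class RunConfig:
    """Paths and parameters for a full pipeline run."""

    tree: str
    orthogroups: str
    annotation: str
    focal: str
    out_dir: str
    fitness: Optional[str] = None
    strata: Optional[str] = None       # YAML: list of per-ancestor categories
    genome_length: Optional[int] = None  # default: max annotated end coordinate
    B: int = 100
    W: int = 20
    tau: float = DEFAULT_TAU
    rule: str = "yield"
    root_method: str = "midpoint"      # or "none" to take the tree as-is
    seed: int = 0
    n_permutations: int = 10_000

    def validate(self) -> None:
        problems = []
        if self.B < 1:
            problems.append(f"B must be >= 1, got {self.B}")
        if self.W < 1:
            problems.append(f"W must be >= 1, got {self.W}")
        if not (0 < self.tau <= 1):
            problems.append(f"tau must be in (0, 1], got {self.tau}")
        if self.root_method not in ("midpoint", "none"):
            problems.append(f"unknown root_method {self.root_method!r}")
        if problems:
            raise ValidationError("; ".join(problems))

    @classmethod
    def from_yaml(cls, path, **overrides) -> "RunConfig":
        import yaml

        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**raw)


def _cross_validate(tree, table, annotation, fitness, focal) -> None:
    problems: List[str] = []
    leaves = set(tree.leaf_labels)
    if focal not in leaves:
        problems.append(f"focal taxon {focal!r} is not a leaf of the tree")
    for t in table.taxa:
        if t not in leaves:
            problems.append(f"orthogroup taxon {t!r} not found among tree leaves")
    annotated = {g.gene_id for g in annotation}
    table_genes = set(table.gene_index(focal)) if focal in table.taxa else set()
    for g in sorted(table_genes - annotated)[:10]:
        problems.append(f"orthogroup gene {g!r} absent from the annotation")
    if fitness is not None:
        for g in sorted(set(fitness["gene_id"]) - annotated)[:10]:
            problems.append(f"fitness gene {g!r} absent from the annotation")
    if problems:
        raise ValidationError("input validation failed:\n  " + "\n  ".join(problems))


def run_full(config: RunConfig) -> Dict:
    """Execute the whole pipeline and write reports under ``config.out_dir``.

    Returns a summary dict (also written as ``report.json``).
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    tree = Tree.from_file(config.tree)
    if config.root_method == "midpoint":
        tree = tree.midpoint_root()
    table = OrthogroupTable.from_tsv(config.orthogroups)
    annotation = vio.read_annotation(config.annotation)
    fitness = vio.read_fitness_tsv(config.fitness) if config.fitness else None
    _cross_validate(tree, table, annotation, fitness, config.focal)

    if config.strata:
        import yaml

        with open(config.strata, "r", encoding="utf-8") as fh:
            cats = yaml.safe_load(fh)
        strata = StrataMap.collapsed(tree, config.focal, cats)
    else:
        strata = StrataMap.identity(tree, config.focal)

    tree.to_file(out / "rooted.nwk")

    # Ancestry scores for every annotated gene (unlisted genes score 0).
    gene_ids = [g.gene_id for g in annotation]
    scores = score_all(table, tree, config.focal, strata, gene_ids=gene_ids)
    scores.to_tsv(out / "scores.tsv")

    # Density profile along the genome.
    genome_length = config.genome_length or max(g.end for g in annotation)
    bins = assign_bins(annotation, genome_length, config.B)
    profile = category_fractions(bins, scores, config.B, strata.S, genome_length)
    profile = smooth_profile(profile, config.W)
    profile.to_tsv(out / "density.tsv", seed=config.seed)
    positions = [g.midpoint for g in annotation]
    rho, pval = position_trend(
        positions,
        [scores.score[g.gene_id] for g in annotation],
        n_permutations=config.n_permutations,
        seed=config.seed,
    )

    # Branch-wise duplication rates.
    matrix = copy_numbers(table)
    dup_report = normalize_duplications(infer_branch_duplications(matrix, tree))
    dup_report.to_tsv(out / "duplications.tsv")

    summary: Dict = {
        "config": dataclasses.asdict(config),
        "seed": config.seed,
        "n_genes": len(annotation),
        "S": strata.S,
        "genome_length": genome_length,
        "position_trend": {"rho": rho, "p": pval},
        "total_duplications": int(dup_report.table["dup_count"].sum()),
        "stages": {"essentiality": fitness is not None},
    }

    if fitness is not None:
        records = classify_essential(fitness, tau=config.tau, rule=config.rule)
        depth = depth_phenotype_summary(records, scores)
        depth.to_tsv(out / "depth_summary.tsv", out / "depth_tests.tsv")
        ordinals = {g.gene_id: g.ordinal for g in annotation}
        try:
            core = core_region(records, ordinals)
        except ValueError:
            core = None
        summary["essentiality"] = {
            "n_essential": int(records["essential"].sum()),
            "fraction_essential": float(records["essential"].mean()),
            "core_region_ordinals": list(core) if core else None,
        }
        records.to_csv(out / "essentiality.tsv", sep="\t", index=False)

    with open(out / "report.json", "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=1, default=str)
        fh.write("\n")
    return summary
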