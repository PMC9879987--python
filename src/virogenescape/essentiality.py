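"""Knockout-phenotype classification and its association with conservation depth.

A CRISPR knockout screen yields, per gene, the relative virion yield at
24 h post-infection (on-target / off-target gRNA control, MOI = 1), and
optionally whether a knockout clone could be recovered and whether a large
deletion spanning the locus was viable.  Genes are classified essential by a
yield threshold (default tau = 0.01, i.e. a hundred-fold drop), by clone
recoverability, or by both; phenotypes are then summarized per ancestry
category (n, median yield, fraction essential) with pairwise two-sample
t tests (raw and Benjamini-Hochberg adjusted).  The essential core region is
the smallest ordinal interval covering every deletion-inviable locus.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .ancestry import AncestryAssignment

__all__ = [
    "DepthPhenotypeSummary",
    "classify_essential",
    "depth_phenotype_summary",
    "two_sample_t",
    "core_region",
    "copy_ratio_5p_3p",
    "read_fitness_tsv",
    "write_fitness_tsv",
]

#: Default essentiality threshold on relative yield (hundred-fold reduction).
DEFAULT_TAU = 0.01

_FITNESS_COLUMNS = ["gene_id", "relative_yield", "ko_clonable", "large_deletion_viable"]


def read_fitness_tsv(path) -> pd.DataFrame:
    """Fitness table: gene_id, relative_yield, optional boolean flags."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str}, comment="#")
    if "gene_id" not in df.columns or "relative_yield" not in df.columns:
        raise ValueError(f"fitness table {path}: needs gene_id and relative_yield columns")
    if (df["relative_yield"] < 0).any():
        bad = df.loc[df["relative_yield"] < 0, "gene_id"].tolist()
        raise ValueError(f"negative relative_yield for gene(s): {', '.join(bad)}")
    for col in ("ko_clonable", "large_deletion_viable"):
        if col in df.columns:
            df[col] = df[col].map(
                {True: True, False: False, "True": True, "False": False,
                 "true": True, "false": False, "": pd.NA, "NA": pd.NA}
            ).astype("boolean")
        else:
            df[col] = pd.Series(pd.NA, index=df.index, dtype="boolean")
    return df[_FITNESS_COLUMNS + [c for c in df.columns if c not in _FITNESS_COLUMNS]]


def write_fitness_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def classify_essential(
    records: pd.DataFrame, tau: float = DEFAULT_TAU, rule: str = "yield"
) -> pd.DataFrame:
    """Add an ``essential`` column under the chosen classification rule.

    rule='yield': relative_yield < tau; rule='clonability': knockout clone not
    recoverable; rule='combined': both (requires both fields on every row).
    """
    if not (0 < tau <= 1):
        raise ValueError(f"tau must be in (0, 1], got {tau}")
    if rule not in ("yield", "clonability", "combined"):
        raise ValueError(f"unknown classification rule {rule!r}")
    out = records.copy()
    by_yield = out["relative_yield"] < tau
    if rule == "yield":
        out["essential"] = by_yield
        return out
    missing = out.loc[out["ko_clonable"].isna(), "gene_id"].tolist()
    if missing:
        raise ValueError(
            f"rule={rule!r} needs ko_clonable flags; missing for: {', '.join(missing)}"
        )
    by_clone = ~out["ko_clonable"].astype(bool)
    out["essential"] = by_clone if rule == "clonability" else (by_clone & by_yield)
    out["essential"] = out["essential"].astype(bool)
    return out


def two_sample_t(
    a: Sequence[float], b: Sequence[float], variant: str = "student"
) -> Tuple[float, float, float]:
    """Unpaired two-tailed two-sample t test; returns (t, df, p).

    variant='student' pools variances (df = n_a + n_b - 2); variant='welch'
    uses the Welch-Satterthwaite df.  Degenerate zero-variance input: equal
    means give (0, df, 1); unequal means give p = 0 (infinite t).
    """
    x = np.asarray(a, dtype=float)
    y = np.asarray(b, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each sample needs at least 2 observations")
    if variant not in ("student", "welch"):
        raise ValueError(f"unknown t-test variant {variant!r}")
    nx, ny = x.size, y.size
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    diff = x.mean() - y.mean()
    if variant == "student":
        df = nx + ny - 2.0
        pooled = ((nx - 1) * vx + (ny - 1) * vy) / df
        se = math.sqrt(pooled * (1 / nx + 1 / ny))
    else:
        se = math.sqrt(vx / nx + vy / ny)
        if se > 0:
            df = (vx / nx + vy / ny) ** 2 / (
                (vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1)
            )
        else:
            df = nx + ny - 2.0
    if se == 0:
        if diff == 0:
            return 0.0, df, 1.0
        return math.copysign(math.inf, diff), df, 0.0
    t = diff / se
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(df), float(p)


@dataclass
class DepthPhenotypeSummary:
    """Phenotype by ancestry category plus pairwise between-category tests."""

    per_category: pd.DataFrame  # category, n, median_yield, n_essential, fraction_essential
    pairwise: pd.DataFrame      # cat_a, cat_b, t, df, p, p_bh

    def to_tsv(self, path_summary, path_tests=None) -> None:
        self.per_category.to_csv(path_summary, sep="\t", index=False, float_format="%.6g")
        if path_tests is not None:
            self.pairwise.to_csv(path_tests, sep="\t", index=False, float_format="%.6g")


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    m = p.size
    order = np.argsort(p)
    adj = np.empty(m)
    running = 1.0
    for rank in range(m - 1, -1, -1):
        idx = order[rank]
        running = min(running, p[idx] * m / (rank + 1))
        adj[idx] = running
    return adj


def depth_phenotype_summary(
    records: pd.DataFrame,
    scores: AncestryAssignment,
    variant: str = "student",
) -> DepthPhenotypeSummary:
    """Summarize knockout phenotypes per ancestry category.

    Every record must carry an ``essential`` label (see
    :func:`classify_essential`) and a score in *scores*.  Categories with no
    genes are kept with n = 0 and NaN statistics so the full 0..S range is
    always reported.
    """
    if "essential" not in records.columns:
        raise ValueError("records lack an 'essential' column; classify first")
    unscored = [g for g in records["gene_id"] if g not in scores.score]
    if unscored:
        raise ValueError(f"genes without ancestry scores: {', '.join(unscored[:10])}")
    df = records.copy()
    df["category"] = df["gene_id"].map(scores.score)

    rows = []
    groups: Dict[int, np.ndarray] = {}
    for c in range(scores.S + 1):
        grp = df[df["category"] == c]
        groups[c] = grp["relative_yield"].to_numpy()
        rows.append(
            {
                "category": c,
                "n": len(grp),
                "median_yield": grp["relative_yield"].median() if len(grp) else np.nan,
                "n_essential": int(grp["essential"].sum()) if len(grp) else 0,
                "fraction_essential": grp["essential"].mean() if len(grp) else np.nan,
            }
        )
    per_category = pd.DataFrame(rows)

    pairs = []
    for ca, cb in combinations(range(scores.S + 1), 2):
        if groups[ca].size >= 2 and groups[cb].size >= 2:
            t, dof, p = two_sample_t(groups[ca], groups[cb], variant=variant)
            pairs.append({"cat_a": ca, "cat_b": cb, "t": t, "df": dof, "p": p})
    pairwise = pd.DataFrame(pairs, columns=["cat_a", "cat_b", "t", "df", "p"])
    if len(pairwise):
        pairwise["p_bh"] = _benjamini_hochberg(pairwise["p"].to_numpy())
    else:
        pairwise["p_bh"] = pd.Series(dtype=float)
    return DepthPhenotypeSummary(per_category=per_category, pairwise=pairwise)


def core_region(records: pd.DataFrame, ordinals: Dict[str, int]) -> Tuple[int, int]:
    """Smallest closed ordinal interval covering all deletion-inviable loci.

    ``ordinals`` maps gene IDs to their rank along the genome.  Raises if no
    locus is flagged deletion-inviable (large_deletion_viable = False).
    """
    inviable = records[records["large_deletion_viable"] == False]  # noqa: E712 (nullable)
    if inviable.empty:
        raise ValueError("no core detected: no locus is flagged deletion-inviable")
    missing = [g for g in inviable["gene_id"] if g not in ordinals]
    if missing:
        raise ValueError(f"inviable loci missing from the annotation: {', '.join(missing)}")
    ranks = [ordinals[g] for g in inviable["gene_id"]]
    return min(ranks), max(ranks)


def copy_ratio_5p_3p(copies_5p: float, copies_3p: float) -> float:
    """qPCR copy-number ratio between a 5' and a 3' marker locus.

    Infinite (complete 3' loss) when the 3' copy number is zero.
    """
    if copies_5p < 0 or copies_3p < 0:
        raise ValueError("copy numbers must be non-negative")
    if copies_3p == 0:
        return math.inf
    return copies_5p / copies_3p
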