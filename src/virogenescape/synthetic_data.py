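"""Genomic-accordion simulator: gene gain/loss/duplication along a species tree.

Emulates the study system — a focal pandoravirus-like genome inside a
three-clade tree (phycodnavirus-like outgroup, mollivirus-like clade,
pandoravirus-like clade) — with:

* gene families gained, lost and duplicated along branches (independent
  Poisson processes per family per branch);
* genome layout in which young genes are positionally biased toward the 3'
  end (per-category Beta law on the midpoint quantile);
* knockout fitness in which ancient genes are more often essential
  (monotone per-category essentiality probabilities), plus a planted
  deletion-intolerant core interval at the 5' end.

Every simulated quantity is recorded as ground truth so the pipeline's
inference (ancestry scores, duplication counts, positional trend, core
region) can be tested for recovery.  All randomness flows through one
``numpy.random.Generator`` seeded from the config, so outputs are exactly
reproducible from ``(config, seed)``.
"""

from __future__ import annotations

import dataclasses
import json
import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .ancestry import OrthogroupTable, StrataMap
from .genomescape import GeneAnnotation
from .phylo import Tree

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "SimulatedDataset",
    "DEFAULT_TREE_NEWICK",
    "simulate_tree",
    "simulate_gene_histories",
    "layout_genome",
    "simulate_fitness",
    "simulate_dataset",
    "write_dataset",
]

#: Default 12-leaf study-structure tree: a focal pandoravirus-like leaf with
#: 5 relatives, 2 mollivirus-like and 4 phycodnavirus-like taxa.  The focal
#: leaf sits at depth 5, so the identity strata map yields categories 0-5.
DEFAULT_TREE_NEWICK = (
    "((((("
    "P_neocaledonia:0.40,P_kuranda:0.30):0.08,"
    "(P_dulcis:0.25,P_quercus:0.25):0.08):0.08,"
    "(P_salinus:0.30,P_macleodensis:0.30):0.12):0.12,"
    "(M_sibericum:0.25,M_kamchatka:0.25):0.30):0.10,"
    "((Phy_EhV86:0.60,Phy_EsV1:0.55):0.20,"
    "(Phy_OtV1:0.55,Phy_PBCV1:0.50):0.20):0.35);"
)

DEFAULT_FOCAL = "P_neocaledonia"


@dataclass
class SimulationConfig:
    """All knobs of the generator; defaults are the study conditions.

    Rates are events per unit branch length: ``gain_rate`` for new-family
    births per lineage, ``loss_rate``/``dup_rate`` per existing family.
    ``insertion_bias`` maps ancestry category to the Beta(alpha, beta) law of
    the gene-midpoint quantile (category 0 is 3'-skewed by default);
    ``essentiality_model`` gives the essentiality probability per category,
    non-decreasing with age.
    """

    seed: int = 0
    tree_spec: Union[None, str, Dict] = None  # None -> default fixed tree
    focal: str = DEFAULT_FOCAL
    gain_rate: float = 400.0
    loss_rate: float = 0.2
    dup_rate: float = 0.15
    n_ancestral_genes: int = 150
    genome_length: int = 2_000_000
    gene_length: int = 1_000
    insertion_bias: Dict[int, Tuple[float, float]] = field(
        default_factory=lambda: {
            0: (5.0, 1.0),
            1: (2.0, 1.0),
            2: (1.0, 1.0),
            3: (1.0, 1.5),
            4: (1.0, 3.0),
            5: (1.0, 4.0),
        }
    )
    essentiality_model: Sequence[float] = (0.05, 0.10, 0.20, 0.40, 0.60, 0.80)
    yield_noise: float = 0.25     # lognormal sigma for dispensable-gene yields
    tau_true: float = 0.01        # essential genes yield Uniform(0, tau_true)
    core_interval: Tuple[float, float] = (0.02, 0.40)  # planted core, genome fractions

    def validate(self) -> None:
        if self.gain_rate < 0 or self.loss_rate < 0 or self.dup_rate < 0:
            raise ValueError("rates must be non-negative")
        pe = list(self.essentiality_model)
        if any(not (0 <= p <= 1) for p in pe):
            raise ValueError("essentiality probabilities must lie in [0, 1]")
        if any(b < a for a, b in zip(pe, pe[1:])):
            raise ValueError("essentiality probabilities must be non-decreasing")
        lo, hi = self.core_interval
        if not (0 <= lo < hi <= 1):
            raise ValueError("core_interval must be a fraction pair 0 <= lo < hi <= 1")

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        import yaml

        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        if "insertion_bias" in raw:
            raw["insertion_bias"] = {
                int(k): tuple(v) for k, v in raw["insertion_bias"].items()
            }
        if "core_interval" in raw:
            raw["core_interval"] = tuple(raw["core_interval"])
        return cls(**raw)

    def to_jsonable(self) -> Dict:
        d = dataclasses.asdict(self)
        d["insertion_bias"] = {str(k): list(v) for k, v in self.insertion_bias.items()}
        d["essentiality_model"] = list(self.essentiality_model)
        d["core_interval"] = list(self.core_interval)
        return d


@dataclass
class GroundTruth:
    """Everything the simulator knows: per-gene birth strata, positions and
    essentiality; per-branch duplication/loss event counts (focal families
    only); the planted core interval."""

    genes: pd.DataFrame          # gene_id, family, true_stratum, essential, ...
    branch_events: pd.DataFrame  # branch, dup_count, loss_count
    core_interval_bp: Tuple[int, int]
    seed: int

    def to_json(self, path) -> None:
        payload = {
            "seed": self.seed,
            "core_interval_bp": list(self.core_interval_bp),
            "genes": self.genes.to_dict(orient="records"),
            "branch_events": self.branch_events.to_dict(orient="records"),
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=1, default=_json_default)
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path, "r", encoding="utf-8") as fh:
            payload = json.load(fh)
        return cls(
            genes=pd.DataFrame(payload["genes"]),
            branch_events=pd.DataFrame(payload["branch_events"]),
            core_interval_bp=tuple(payload["core_interval_bp"]),
            seed=payload["seed"],
        )


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


@dataclass
class SimulatedDataset:
    """Bundle of pipeline inputs plus ground truth for one simulation."""

    config: SimulationConfig
    tree: Tree
    orthogroups: OrthogroupTable
    annotation: List[GeneAnnotation]
    fitness: pd.DataFrame
    truth: GroundTruth


def simulate_tree(config: SimulationConfig, rng: Optional[np.random.Generator] = None) -> Tree:
    """The species tree: the fixed default, a user Newick, or a birth-death draw."""
    spec = config.tree_spec
    if spec is None:
        return Tree.from_newick(DEFAULT_TREE_NEWICK)
    if isinstance(spec, str):
        return Tree.from_newick(spec)
    if isinstance(spec, dict):
        from dendropy.simulate import treesim

        rng = rng or np.random.default_rng(config.seed)
        pyrng = random.Random(int(rng.integers(0, 2**31 - 1)))
        dtree = treesim.birth_death_tree(
            birth_rate=float(spec.get("birth_rate", 1.0)),
            death_rate=float(spec.get("death_rate", 0.0)),
            num_extant_tips=int(spec["n_leaves"]),
            rng=pyrng,
        )
        for i, leaf in enumerate(dtree.leaf_node_iter()):
            leaf.taxon.label = config.focal if i == 0 else f"taxon_{i}"
        return Tree(dtree)
    raise TypeError(f"unsupported tree_spec: {spec!r}")


def simulate_gene_histories(
    tree: Tree, config: SimulationConfig, rng: np.random.Generator
) -> Tuple[OrthogroupTable, GroundTruth]:
    """Evolve gene-family copy numbers along the tree.

    Ancestral families start at the root with one copy.  On every branch of
    length l, each family with c > 0 parent copies draws ``D ~ Pois(dup*l)``
    duplications and ``L ~ Pois(loss*l)`` losses (child count
    ``max(0, c + D - L)``), and ``G ~ Pois(gain*l)`` brand-new families are
    born with one copy.  The emitted orthogroup table is restricted to
    families with at least one focal copy; the returned ground truth records
    the birth stratum of every focal family and per-branch duplication/loss
    events of focal families.
    """
    config.validate()
    focal = config.focal
    if focal not in set(tree.leaf_labels):
        raise ValueError(f"focal taxon {focal!r} is not a leaf of the tree")

    strata = StrataMap.identity(tree, focal)
    path_ids = set(strata.category_of)

    fam_birth: Dict[str, int] = {}          # family -> id(birth node)
    fam_events: Dict[str, List[Tuple[str, int, int]]] = {}  # family -> (branch, dup, loss)
    counts_at: Dict[int, Dict[str, int]] = {}  # id(node) -> family -> copies
    n_fams = 0

    def new_family(birth_node) -> str:
        nonlocal n_fams
        fam = f"OG{n_fams:05d}"
        n_fams += 1
        fam_birth[fam] = id(birth_node)
        fam_events[fam] = []
        return fam

    root = tree.root
    counts_at[id(root)] = {}
    for _ in range(config.n_ancestral_genes):
        counts_at[id(root)][new_family(root)] = 1

    for node in tree.nodes():
        if node is root:
            continue
        ell = tree.branch_length(node)
        parent_counts = counts_at[id(node.parent_node)]
        branch = tree.label_of(node)
        child_counts: Dict[str, int] = {}
        for fam in sorted(parent_counts):
            c = parent_counts[fam]
            if c <= 0:
                continue
            d = int(rng.poisson(config.dup_rate * ell))
            l = int(rng.poisson(config.loss_rate * ell))
            new_c = max(0, c + d - l)
            if d or l:
                fam_events[fam].append((branch, d, min(l, c + d)))
            if new_c > 0:
                child_counts[fam] = new_c
        for _ in range(int(rng.poisson(config.gain_rate * ell))):
            child_counts[new_family(node)] = 1
        counts_at[id(node)] = child_counts

    leaf_counts = {lbl: counts_at[id(tree.leaf(lbl))] for lbl in tree.leaf_labels}
    focal_fams = sorted(f for f, c in leaf_counts[focal].items() if c > 0)

    # Orthogroup table restricted to focal families; gene IDs per taxon copy.
    taxa = list(tree.leaf_labels)
    per_taxon_counter = {t: 0 for t in taxa}
    membership: Dict[str, Dict[str, List[str]]] = {}
    gene_rows = []
    for fam in focal_fams:
        row: Dict[str, List[str]] = {}
        for t in taxa:
            k = leaf_counts[t].get(fam, 0)
            ids = []
            for _ in range(k):
                per_taxon_counter[t] += 1
                ids.append(f"{t}_g{per_taxon_counter[t]:04d}")
            row[t] = ids
        membership[fam] = row
        birth = fam_birth[fam]
        if birth in path_ids:
            stratum = strata.category_of[birth]
        elif birth == id(tree.leaf(focal)):
            stratum = 0
        else:  # born at the root
            stratum = strata.S if birth == id(root) else 0
        for gid in row[focal]:
            gene_rows.append({"gene_id": gid, "family": fam, "true_stratum": stratum})

    table = OrthogroupTable(taxa=taxa, membership=membership)

    # Per-branch event totals over emitted (focal) families.  ``birth_count``
    # is kept separate from duplications proper: under copy-number parsimony a
    # family birth also appears as a 0 -> 1 increase on its birth branch, so
    # recovery comparisons need dup_count + birth_count.
    branch_labels = [tree.label_of(n) for n in tree.nodes() if n is not root]
    label_by_id = {id(n): tree.label_of(n) for n in tree.nodes()}
    dup_tot = {b: 0 for b in branch_labels}
    loss_tot = {b: 0 for b in branch_labels}
    birth_tot = {b: 0 for b in branch_labels}
    for fam in focal_fams:
        for branch, d, l in fam_events[fam]:
            dup_tot[branch] += d
            loss_tot[branch] += l
        birth_label = label_by_id[fam_birth[fam]]
        if birth_label in birth_tot:  # root-born families have no birth branch
            birth_tot[birth_label] += 1
    branch_events = pd.DataFrame(
        {
            "branch": branch_labels,
            "dup_count": [dup_tot[b] for b in branch_labels],
            "loss_count": [loss_tot[b] for b in branch_labels],
            "birth_count": [birth_tot[b] for b in branch_labels],
        }
    )
    truth = GroundTruth(
        genes=pd.DataFrame(gene_rows, columns=["gene_id", "family", "true_stratum"]),
        branch_events=branch_events,
        core_interval_bp=(0, 0),  # filled after layout
        seed=config.seed,
    )
    return table, truth


def layout_genome(
    truth: GroundTruth, config: SimulationConfig, rng: np.random.Generator
) -> List[GeneAnnotation]:
    """Place focal genes on the genome with category-dependent position bias.

    Each gene's midpoint quantile is drawn from its category's Beta law;
    overlaps are resolved by rejection sampling.  Ordinals follow position.
    """
    genes = truth.genes
    n = len(genes)
    L, glen = config.genome_length, config.gene_length
    if n * glen >= L:
        raise ValueError(
            f"genome too short: {n} genes x {glen} bp exceed {L} bp"
        )
    max_cat = max(config.insertion_bias)
    occupied_starts: List[int] = []
    occupied_ends: List[int] = []
    import bisect

    placed = {}
    for gene_id, cat in zip(genes["gene_id"], genes["true_stratum"]):
        alpha, beta = config.insertion_bias[min(int(cat), max_cat)]
        for _ in range(1000):
            q = rng.beta(alpha, beta)
            mid = q * L
            start = int(round(mid - glen / 2))
            start = min(max(start, 1), L - glen + 1)
            end = start + glen - 1
            i = bisect.bisect_left(occupied_starts, start)
            ok = (i == len(occupied_starts) or occupied_starts[i] > end) and (
                i == 0 or occupied_ends[i - 1] < start
            )
            if ok:
                occupied_starts.insert(i, start)
                occupied_ends.insert(i, end)
                placed[gene_id] = (start, end)
                break
        else:
            raise ValueError("genome too crowded: could not place gene without overlap")

    order = sorted(placed, key=lambda g: placed[g][0])
    strands = rng.choice(["+", "-"], size=n)
    ann = [
        GeneAnnotation(
            gene_id=g,
            start=placed[g][0],
            end=placed[g][1],
            strand=str(strands[k]),
            ordinal=k + 1,
        )
        for k, g in enumerate(order)
    ]
    pos = {a.gene_id: a for a in ann}
    truth.genes["start"] = truth.genes["gene_id"].map(lambda g: pos[g].start)
    truth.genes["end"] = truth.genes["gene_id"].map(lambda g: pos[g].end)
    truth.genes["ordinal"] = truth.genes["gene_id"].map(lambda g: pos[g].ordinal)
    lo, hi = config.core_interval
    truth.core_interval_bp = (int(lo * L) + 1, int(hi * L))
    return ann


def simulate_fitness(
    truth: GroundTruth, config: SimulationConfig, rng: np.random.Generator
) -> pd.DataFrame:
    """Knockout phenotypes: essentiality probability rises with gene age.

    Essential genes yield Uniform(0, tau_true); dispensable genes yield
    LogNormal(0, sigma).  Loci inside the planted core interval are flagged
    deletion-inviable.
    """
    pe = list(config.essentiality_model)
    genes = truth.genes
    cats = genes["true_stratum"].to_numpy()
    probs = np.array([pe[min(int(c), len(pe) - 1)] for c in cats])
    essential = rng.random(len(genes)) < probs
    yields = np.where(
        essential,
        rng.uniform(0.0, config.tau_true, size=len(genes)),
        rng.lognormal(mean=0.0, sigma=config.yield_noise, size=len(genes)),
    )
    lo_bp, hi_bp = truth.core_interval_bp
    mid = (genes["start"].to_numpy() + genes["end"].to_numpy()) / 2.0
    in_core = (mid >= lo_bp) & (mid <= hi_bp)
    truth.genes["essential"] = essential
    records = pd.DataFrame(
        {
            "gene_id": genes["gene_id"],
            "relative_yield": np.clip(yields, 0.0, None),
            "ko_clonable": pd.array(~essential, dtype="boolean"),
            "large_deletion_viable": pd.array(~in_core, dtype="boolean"),
        }
    )
    return records


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Run the full generator: tree, gene histories, layout, fitness."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    tree = simulate_tree(config, rng)
    table, truth = simulate_gene_histories(tree, config, rng)
    annotation = layout_genome(truth, config, rng)
    fitness = simulate_fitness(truth, config, rng)
    return SimulatedDataset(
        config=config,
        tree=tree,
        orthogroups=table,
        annotation=annotation,
        fitness=fitness,
        truth=truth,
    )


def write_dataset(dataset: SimulatedDataset, directory) -> Dict[str, Path]:
    """Write all pipeline inputs plus ground truth and a manifest."""
    from . import io as vio

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "tree": directory / "tree.nwk",
        "orthogroups": directory / "orthogroups.tsv",
        "annotation": directory / "genes.gff3",
        "fitness": directory / "fitness.tsv",
        "ground_truth": directory / "ground_truth.json",
        "manifest": directory / "manifest.json",
    }
    dataset.tree.to_file(paths["tree"])
    dataset.orthogroups.to_tsv(paths["orthogroups"])
    vio.write_gff3(
        dataset.annotation, paths["annotation"], genome_length=dataset.config.genome_length
    )
    vio.write_fitness_tsv(dataset.fitness, paths["fitness"])
    dataset.truth.to_json(paths["ground_truth"])
    manifest = {
        "seed": dataset.config.seed,
        "config": dataset.config.to_jsonable(),
        "files": {k: p.name for k, p in paths.items() if k != "manifest"},
        "n_genes": len(dataset.annotation),
        "n_orthogroups": len(dataset.orthogroups.membership),
    }
    with open(paths["manifest"], "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=1)
        fh.write("\n")
    return paths
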