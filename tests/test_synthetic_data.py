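"""Genomic-accordion generator: determinism, ground truth, recovery hooks."""

import json

import numpy as np
import pandas as pd
import pytest

from virogenescape.ancestry import StrataMap, score_all
from virogenescape.genomescape import position_trend
from virogenescape.phylo import Tree
from virogenescape.synthetic_data import (
    DEFAULT_FOCAL,
    DEFAULT_TREE_NEWICK,
    GroundTruth,
    SimulationConfig,
    layout_genome,
    simulate_dataset,
    simulate_fitness,
    simulate_gene_histories,
    simulate_tree,
    write_dataset,
)


class TestSimulateTree:
    def test_fixed_newick_verbatim(self):
        cfg = SimulationConfig(tree_spec="((A:1,B:2):1,C:3);", focal="A")
        t = simulate_tree(cfg)
        assert sorted(t.leaf_labels) == ["A", "B", "C"]
        assert t.branch_length(t.leaf("C")) == 3.0

    def test_default_tree_structure(self):
        t = simulate_tree(SimulationConfig())
        assert t.n_leaves() == 12
        assert len(t.strata_path(DEFAULT_FOCAL)) == 5  # six categories incl. 0

    def test_same_seed_same_tree(self):
        spec = {"n_leaves": 12, "birth_rate": 1.0, "death_rate": 0.0}
        a = simulate_tree(SimulationConfig(seed=5, tree_spec=spec))
        b = simulate_tree(SimulationConfig(seed=5, tree_spec=spec))
        assert a.to_newick() == b.to_newick()
        assert a.n_leaves() == 12


class TestGeneHistories:
    def test_no_loss_presence_equals_birth_clade(self):
        cfg = SimulationConfig(seed=3, loss_rate=0.0, dup_rate=0.0)
        tree = simulate_tree(cfg)
        table, truth = simulate_gene_histories(tree, cfg, np.random.default_rng(cfg.seed))
        strata = StrataMap.identity(tree, cfg.focal)
        scores = score_all(table, tree, cfg.focal, strata)
        expected = dict(zip(truth.genes["gene_id"], truth.genes["true_stratum"]))
        assert scores.score == expected

    def test_all_rates_zero_everything_ancestral(self):
        cfg = SimulationConfig(seed=4, gain_rate=0.0, loss_rate=0.0, dup_rate=0.0)
        tree = simulate_tree(cfg)
        table, truth = simulate_gene_histories(tree, cfg, np.random.default_rng(cfg.seed))
        assert len(table.membership) == cfg.n_ancestral_genes
        assert set(truth.genes["true_stratum"]) == {5}
        strata = StrataMap.identity(tree, cfg.focal)
        scores = score_all(table, tree, cfg.focal, strata)
        assert set(scores.score.values()) == {5}

    def test_emitted_families_all_have_focal_copy(self, default_dataset):
        focal = default_dataset.config.focal
        for og, row in default_dataset.orthogroups.membership.items():
            assert row[focal], f"{og} has no focal gene"

    def test_invalid_rates_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(loss_rate=-1).validate()
        with pytest.raises(ValueError):
            SimulationConfig(essentiality_model=(0.5, 0.1)).validate()


class TestLayoutGenome:
    def _truth(self, n, cat):
        return GroundTruth(
            genes=pd.DataFrame(
                {
                    "gene_id": [f"g{i}" for i in range(n)],
                    "family": ["OG0"] * n,
                    "true_stratum": [cat] * n,
                }
            ),
            branch_events=pd.DataFrame(),
            core_interval_bp=(0, 0),
            seed=0,
        )

    def test_3prime_bias_mean_quantile(self):
        # sparse genome so overlap rejection does not distort the Beta law
        cfg = SimulationConfig(genome_length=100_000_000)
        truth = self._truth(1000, 0)  # category 0: Beta(5, 1), mean 5/6
        ann = layout_genome(truth, cfg, np.random.default_rng(0))
        mean_q = np.mean([g.midpoint / cfg.genome_length for g in ann])
        assert mean_q == pytest.approx(5 / 6, abs=0.02)

    def test_uniform_control_no_trend(self):
        cfg = SimulationConfig(genome_length=10_000_000)
        cfg.insertion_bias = {**cfg.insertion_bias, 2: (1.0, 1.0)}
        truth = self._truth(500, 2)
        ann = layout_genome(truth, cfg, np.random.default_rng(1))
        mean_q = np.mean([g.midpoint / cfg.genome_length for g in ann])
        assert mean_q == pytest.approx(0.5, abs=0.05)

    def test_no_overlaps_and_ordinals_follow_position(self, default_dataset):
        ann = sorted(default_dataset.annotation, key=lambda g: g.start)
        for prev, nxt in zip(ann, ann[1:]):
            assert prev.end < nxt.start
        assert [g.ordinal for g in ann] == list(range(1, len(ann) + 1))

    def test_same_seed_identical_coordinates(self):
        cfg = SimulationConfig(genome_length=1_000_000)
        t1 = self._truth(100, 0)
        t2 = self._truth(100, 0)
        a1 = layout_genome(t1, cfg, np.random.default_rng(7))
        a2 = layout_genome(t2, cfg, np.random.default_rng(7))
        assert a1 == a2

    def test_overfull_genome_rejected(self):
        cfg = SimulationConfig(genome_length=50_000, gene_length=1000)
        with pytest.raises(ValueError, match="genome too"):
            layout_genome(self._truth(100, 0), cfg, np.random.default_rng(0))


class TestSimulateFitness:
    def _laid_out_truth(self, per_category, cfg, rng):
        S = 5
        n = per_category * (S + 1)
        truth = GroundTruth(
            genes=pd.DataFrame(
                {
                    "gene_id": [f"g{i}" for i in range(n)],
                    "family": ["OG0"] * n,
                    "true_stratum": [i % (S + 1) for i in range(n)],
                }
            ),
            branch_events=pd.DataFrame(),
            core_interval_bp=(0, 0),
            seed=0,
        )
        layout_genome(truth, cfg, rng)
        return truth

    def test_zero_probability_no_essentials(self):
        cfg = SimulationConfig(essentiality_model=(0.0,) * 6, genome_length=5_000_000)
        rng = np.random.default_rng(0)
        truth = self._laid_out_truth(50, cfg, rng)
        recs = simulate_fitness(truth, cfg, rng)
        from virogenescape.essentiality import classify_essential

        classified = classify_essential(recs, tau=cfg.tau_true)
        assert classified["essential"].sum() == 0

    def test_certain_essentiality_fully_recovered(self):
        cfg = SimulationConfig(essentiality_model=(1.0,) * 6, genome_length=5_000_000)
        rng = np.random.default_rng(0)
        truth = self._laid_out_truth(50, cfg, rng)
        recs = simulate_fitness(truth, cfg, rng)
        from virogenescape.essentiality import classify_essential

        classified = classify_essential(recs, tau=cfg.tau_true)
        assert classified["essential"].all()

    def test_planted_gradient_within_binomial_bounds(self):
        """200 genes per category: observed essential fractions track the
        planted monotone probabilities to within +/- 0.1."""
        cfg = SimulationConfig(genome_length=20_000_000)
        rng = np.random.default_rng(0)
        truth = self._laid_out_truth(200, cfg, rng)
        recs = simulate_fitness(truth, cfg, rng)
        merged = recs.merge(truth.genes[["gene_id", "true_stratum", "essential"]])
        for cat, pe in enumerate(cfg.essentiality_model):
            frac = merged.loc[merged["true_stratum"] == cat, "essential"].mean()
            assert frac == pytest.approx(pe, abs=0.1)

    def test_core_interval_marks_inviable_loci(self, default_dataset):
        ds = default_dataset
        lo, hi = ds.truth.core_interval_bp
        mids = {g.gene_id: g.midpoint for g in ds.annotation}
        for _, row in ds.fitness.iterrows():
            inside = lo <= mids[row["gene_id"]] <= hi
            assert bool(row["large_deletion_viable"]) == (not inside)


class TestWriteDataset:
    def test_roundtrip_and_manifest(self, default_dataset, tmp_path):
        from virogenescape import io as vio
        from virogenescape.ancestry import OrthogroupTable

        paths = write_dataset(default_dataset, tmp_path / "ds")
        assert len(paths) == 6
        tree = Tree.from_file(paths["tree"])
        assert sorted(tree.leaf_labels) == sorted(default_dataset.tree.leaf_labels)
        table = OrthogroupTable.from_tsv(paths["orthogroups"])
        assert table.membership == default_dataset.orthogroups.membership
        ann = vio.read_gff3(paths["annotation"])
        assert ann == sorted(default_dataset.annotation, key=lambda g: g.start)
        fit = vio.read_fitness_tsv(paths["fitness"])
        assert len(fit) == len(default_dataset.fitness)
        truth = GroundTruth.from_json(paths["ground_truth"])
        assert truth.core_interval_bp == default_dataset.truth.core_interval_bp
        manifest = json.loads(paths["manifest"].read_text())
        assert manifest["seed"] == default_dataset.config.seed
        assert manifest["config"]["gain_rate"] == default_dataset.config.gain_rate

    def test_same_seed_byte_identical(self, tmp_path):
        for d in ("a", "b"):
            write_dataset(simulate_dataset(SimulationConfig(seed=9)), tmp_path / d)
        for name in (
            "tree.nwk",
            "orthogroups.tsv",
            "genes.gff3",
            "fitness.tsv",
            "ground_truth.json",
            "manifest.json",
        ):
            assert (tmp_path / "a" / name).read_bytes() == (
                tmp_path / "b" / name
            ).read_bytes()


class TestEndToEndBias:
    def test_young_genes_trend_3prime_single_seed(self, default_dataset):
        ds = default_dataset
        scores = dict(zip(ds.truth.genes["gene_id"], ds.truth.genes["true_stratum"]))
        pos = [g.midpoint for g in ds.annotation]
        sc = [scores[g.gene_id] for g in ds.annotation]
        rho, p = position_trend(pos, sc, seed=0)
        assert rho < 0 and p < 0.05

    def test_mirrored_bias_reverses_trend(self):
        cfg = SimulationConfig(seed=6)
        cfg.insertion_bias = {c: (b, a) for c, (a, b) in cfg.insertion_bias.items()}
        ds = simulate_dataset(cfg)
        scores = dict(zip(ds.truth.genes["gene_id"], ds.truth.genes["true_stratum"]))
        pos = [g.midpoint for g in ds.annotation]
        sc = [scores[g.gene_id] for g in ds.annotation]
        rho, p = position_trend(pos, sc, seed=0)
        assert rho > 0 and p < 0.05
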