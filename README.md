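# virogenescape

Comparative-genomics toolkit for studying how giant-virus genomes expand:
per-gene ancestry (phylostratum) scoring from orthogroups on a species tree,
positional density of gene-age categories along a genome, branch-wise gene
duplication rates, and the association between conservation depth and
gene essentiality measured in CRISPR knockout screens.

It is written for virologists and molecular evolutionists testing the
*genomic accordion* hypothesis — that pandoravirus-scale genomes arose from
smaller phycodnavirus-like ancestors by biased gain, duplication and loss of
genes — against orthology tables, genome annotations and knockout fitness
data.

## The model

**Ancestry scores.** Each focal-genome gene *g* is assigned an integer score

> a(g) = 0 if *g* has no homolog outside the focal genome (an ORFan),
> otherwise the stratum of LCA(T(g)),

where T(g) is the set of taxa whose column in *g*'s orthogroup is non-empty
and strata number the nodes of the focal leaf's root path 1…S (the tree is
midpoint-rooted first when required). On the default 12-taxon
study-structure tree (a focal pandoravirus-like leaf with 5 relatives, 2
mollivirus-like and 4 phycodnavirus-like taxa) the scores run from 0
(strain-specific) to 5 (shared with at least one phycodnavirus-like taxon).

**Density landscape.** The genome is sliced into B = 100 bins; per bin the
fraction of genes of each score category is computed (genes counted once, by
midpoint) and smoothed with a sliding window of W = 20 bins. A Spearman
rank correlation between gene position and score, with a seeded permutation
p-value, quantifies 3′ accumulation of young genes.

**Duplication rates.** Ancestral copy numbers per orthogroup are
reconstructed under linear-cost Wagner/Sankoff parsimony (cost |i − j|,
smallest-state tie-breaks). A duplication on the branch above node *v* is
d_b = max(0, n(v) − n(parent)); branch rates are r_b = d_b / ℓ_b, reported
as log10 r_b.

**Essentiality.** Knockouts are classified essential by relative virion
yield y_g < τ (default τ = 0.01, a hundred-fold drop), by knockout-clone
recoverability, or both; phenotypes are summarized per ancestry category
(n, median yield, fraction essential) with unpaired two-tailed t tests
(Student or Welch; Benjamini–Hochberg-adjusted p alongside raw p). The
essential core region is the smallest gene-ordinal interval covering every
deletion-intolerant locus.

A bundled simulator generates all inputs under this exact generative model —
gains/losses/duplications as Poisson processes along branches, Beta-law
positional bias, a monotone essentiality gradient and a planted core — with
full ground truth for recovery testing.

## Worked example

Simulate a dataset under the default study conditions and run the whole
pipeline on it:

```sh
virogenescape simulate --seed 7 --out example/
virogenescape run-all --config run.yaml --out example_run/
```

or in Python:

```python
import virogenescape as vg

ds = vg.simulate_dataset(vg.SimulationConfig(seed=7))
paths = vg.write_dataset(ds, "example/")
summary = vg.run_full(vg.RunConfig(
    tree=str(paths["tree"]), orthogroups=str(paths["orthogroups"]),
    annotation=str(paths["annotation"]), fitness=str(paths["fitness"]),
    focal="P_neocaledonia", out_dir="example_run/",
    genome_length=2_000_000, root_method="none", seed=7))
```

This prints/reports (from `report.json` and `depth_summary.tsv`):

```
n_genes 464   S 5
position_trend  rho = -0.797, p = 1e-04
total_duplications 505
core_region_ordinals [7, 201]

category   n  median_yield  n_essential  fraction_essential
       0 149      0.920              8             0.054
       1  25      0.956              1             0.040
       2  31      0.888              9             0.290
       3  54      0.880             17             0.315
       4  57      0.008             37             0.649
       5 148      0.006            127             0.858
```

Read: of 464 focal genes, young genes (category 0) pile up toward the 3′
end (rho strongly negative), ancient genes (categories 4–5) have a median
knockout yield near the essentiality threshold and a high essential
fraction, and every deletion-intolerant locus falls between gene ordinals 7
and 201 — the 5′ essential core. All numbers are exactly reproducible from
the seed.

## Layout

- `src/virogenescape/phylo.py` — Newick I/O, midpoint rooting, LCA, root paths
- `src/virogenescape/ancestry.py` — orthogroup tables, strata maps, scoring
- `src/virogenescape/genomescape.py` — binning, density, smoothing, trend, interval arithmetic
- `src/virogenescape/duplications.py` — copy-number parsimony, branch rates
- `src/virogenescape/essentiality.py` — knockout classification, depth summaries, core region
- `src/virogenescape/synthetic_data.py` — the genomic-accordion simulator
- `src/virogenescape/pipeline.py`, `io.py`, `cli.py` — orchestration, formats, CLI

See `docs/methods.md` for the modeling assumptions, parameter defaults and
known limitations.
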