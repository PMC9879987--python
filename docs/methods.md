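# Methods

This note documents the models and procedures implemented in virogenescape,
the defaults and why they were chosen, what the synthetic-data generator
does and does not emulate, and the numerical conventions that matter for
reproducing its output.

## Trees, rooting and strata

Trees are read from Newick (quoted labels and bracket comments are accepted;
missing branch lengths default to 0; duplicate leaf labels and negative
lengths are rejected). Midpoint rooting places the root at the point
minimizing the maximum point-to-leaf patristic distance (equivalently,
halving the longest leaf-to-leaf path). Implementation: for every edge the
maximum leafward and rootward distances are computed in two tree passes and
the per-edge optimum has a closed form, so the global optimum is exact, not
searched. Ties between edges are broken by post-order position; when the
optimum falls inside an edge a new degree-2 root node is inserted and
*kept*, so the focal leaf's depth — and therefore the number of ancestry
strata — is well defined. A previous degree-2 root left stranded by
rerooting is collapsed. Multifurcations are allowed everywhere; the LCA is
defined on the topology as given.

The strata map assigns integer categories to the focal leaf's ancestors.
The default is the identity (i-th ancestor ↦ i), which on the default
12-taxon tree yields exactly six categories 0–5 because the focal leaf sits
at depth 5. For deeper trees a collapse constructor accepts a per-ancestor
category list (non-decreasing, contiguous 1..S), e.g. to group all
within-family nodes into one stratum. The grouping used for any particular
published tree is a user choice, not something the method can infer.

## Ancestry scoring

Presence of a homolog is binary per taxon: a non-empty cell in the gene's
orthogroup row. A gene in no orthogroup, or whose orthogroup contains only
focal-genome paralogs, scores 0. Otherwise the score is the stratum of the
LCA of all taxa with a homolog; because the focal taxon is always a member,
this LCA lies on the focal root path. A gene listed in two orthogroups is
an upstream inconsistency and raises an error rather than being resolved
silently. Scores are monotone in the presence set: adding taxa can only
move the LCA rootward.

## Density landscape

Coordinates are 1-based inclusive (GFF3 convention); BED input is converted
on read. Genes are assigned to one of B bins by midpoint —
`floor((midpoint − 1)/(L/B))`, clipped into range — so the per-bin category
fractions are a true partition of the gene set (binning by overlap would
double-count straddling genes). Whether to bin by midpoint or start is an
arbitrary convention; midpoint was chosen as the less strand-asymmetric
one. Empty bins are flagged undefined (NaN), never treated as zero.

Smoothing is a centered, truncated moving average: the window around bin i
spans `[i − ⌊(W−1)/2⌋, i + ⌊W/2⌋]` clipped to the profile, with undefined
bins excluded from the mean. Defaults B = 100, W = 20. Constant profiles
are fixed points of the smoother, and smoothing commutes with category
relabeling.

The positional trend statistic is the Spearman rank correlation between
gene midpoint and ancestry score. Its p-value is a two-sided permutation
test (default 10,000 label permutations) computed vectorially on midranks;
the permutation seed is recorded in the density output header. With tied
score ranks the permuted statistic is the Pearson correlation of midranks,
which matches Spearman's rho under ties.

## Duplication rates from copy-number parsimony

Ancestral copy numbers per orthogroup are reconstructed by linear-cost
(Wagner/Sankoff) parsimony over states 0..max observed count; capping the
state space at the maximum leaf count is lossless under linear costs.
Root states and top-down assignments break ties toward the smallest state,
which is deterministic and conservative for duplication counts.
Duplications (copy-number increases) and losses (decreases) are summed per
branch over orthogroups, normalized by branch length, and log10-transformed;
rates on zero-length branches and logs of zero counts are flagged undefined
rather than dropped.

Two caveats are inherent to this desk-scale substitute for gene-tree
reconciliation. First, a family's birth appears as a 0→1 increase on its
birth branch, so "duplications" on terminal branches of genomes rich in
young genes include family births; the simulator's ground truth therefore
tracks births separately. Second, parsimony returns the *minimum* change
compatible with the tips: independent gains of the same family on sister
branches can be collapsed onto the parent branch, so inferred totals are a
lower bound on true event counts. Exact per-branch recovery is guaranteed
only for histories without such parallel gains, which is how the recovery
tests are constructed; on simulated data at the default rates the inferred
total is within a few percent of the truth.

## Essentiality

The yield rule classifies a knockout essential when relative virion yield
falls below τ; the default τ = 0.01 encodes a hundred-fold reduction, the
scale of fitness loss observed when core genes are targeted. When
clone-recoverability flags are available the clonability (or combined) rule
is preferable, since yield alone conflates slow growers with true
essentials. Per-category summaries report n, median yield, and the
essential fraction; all pairwise category comparisons use the unpaired
two-tailed t test (pooled-variance Student by default, Welch optional) with
Benjamini–Hochberg adjustment reported alongside raw p-values. Degenerate
zero-variance inputs return t = 0, p = 1 for equal means and a flagged
p = 0 otherwise.

The core region is formalized as the smallest closed interval of gene
ordinals covering every locus flagged deletion-intolerant. This is a
deliberate sharpening of a boundary that experimentalists draw
approximately; it is exact for the simulator's planted core and transparent
for real data.

## The synthetic-data generator

The generator emulates the accordion: a fixed 12-leaf, three-clade tree
(focal pandoravirus-like leaf at depth 5; branch lengths chosen so the
focal terminal branch is long, as in measured pandoravirus trees); gene
families gained at rate γ = 400 per unit branch length per lineage, and per
family lost/duplicated at λ = 0.2 / δ = 0.15 per unit length, starting from
150 root-ancestral families. Under these conditions the focal genome
carries ≈450 genes, roughly a third of them ORFans and a third ancient —
the qualitative shape of a pandoravirus gene-age distribution at half scale
(real genomes have ~1,000 genes; halving keeps the default test suite and
validation runs fast without changing any of the tested statistics, which
are fractions, correlations and interval coverages).

Genome layout draws each gene's midpoint quantile from a per-category Beta
law — Beta(5,1) for ORFans (mean 5/6, 3′-skewed), flat for mid strata,
Beta(1,4) for the most ancient (5′-skewed) — with fixed 1 kb gene length on
a 2 Mb genome and rejection sampling to prevent overlaps. Rejection slightly
compresses extreme bias when local occupancy is high; tests of the Beta law
itself therefore use a sparse genome. Fitness: essentiality is Bernoulli
with probability (0.05, 0.10, 0.20, 0.40, 0.60, 0.80) by category; essential
genes yield Uniform(0, 0.01), dispensable genes LogNormal(0, 0.25); loci
inside the planted core (genome fractions 0.02–0.40) are flagged
deletion-intolerant. Families evolve independently (no linkage, no
synteny), there is no sequence evolution, no horizontal transfer and no
inversion; passing recovery tests therefore demonstrates correctness of the
inference pipeline under the generative model, not robustness to the many
ways real orthology calls and screens are noisy.

All randomness flows through a single `numpy.random.Generator` seeded from
the config, in a fixed traversal order, so every output table is
byte-reproducible from (config, seed).

## Numerical conventions and degenerate inputs

- Branch lengths ≥ 0; all-zero trees make the midpoint undefined (error).
- Root-balance tolerance for midpoint rooting: 1e−9 on the two maximal
  root-to-leaf distances; edge-optimum comparisons use 1e−12.
- Empty density bins: NaN, excluded from window means; a profile with no
  genes anywhere cannot be smoothed (error).
- Constant scores or positions: trend reported as rho = 0, p = 1.
- Interval arithmetic is 1-based inclusive: length = end − start + 1.
- Fractions over categories in any non-empty bin sum to 1 within 1e−9.

## Known limitations

- Copy-number parsimony undercounts parallel gains (see above) and cannot
  see duplication-then-loss cycles on a single branch.
- Ancestry scores are presence-based and not corrected for horizontal
  transfer or annotation gaps; a single spurious ortholog call in a distant
  taxon promotes a gene to the deepest stratum.
- The core-region rule assumes deletion-intolerance flags are trustworthy;
  one mislabeled 3′ locus stretches the interval to cover it.
- The simulator's default conditions are a scaled, idealized stand-in for
  the study system; its parameter values are documented choices, not fitted
  estimates.
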