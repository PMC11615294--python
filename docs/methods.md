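# Methods

`crosschat` detects hierarchical structure in cell–cell communication (CCC)
from single-cell or spatial transcriptomics, from two complementary angles:
a **global** one — a multiscale clustering of cells whose scales index
communication at different resolutions — and a **local** one — rooted trees
of ligands (or receptors) ordered by inclusion of the cell sets that
express them.

## Global hierarchy: Markov-stability clustering

Cells are embedded by PCA of the log-normalized expression matrix (all
genes restricted to highly variable genes, or ligand/receptor genes only),
and a k-nearest-neighbor graph (default k = 15) is built under cosine
similarity, symmetrized by union with negative similarities clipped to
zero.  On this weighted graph with adjacency A and degree matrix D, the
continuous-time random walk has transition matrix P(t) = exp(−tL) with
L = I − D⁻¹A.  For a partition into communities {C_i}, the Markov
stability

    MS(t) = Σ_{u,v in the same community} ( P(t)_{uv} − π_v ),

with π the stationary distribution (π_u = d_u / Σd for an undirected
graph), measures the excess probability that a walker started anywhere is
still inside its starting community after time t.  Useful identities: the
one-block partition has MS = 0 at every t; the singleton partition has
MS = n − 1 at t = 0; for a fixed partition MS is non-increasing in t.
P(t) is evaluated exactly through the eigendecomposition of the symmetric
conjugate D^{−1/2}AD^{−1/2}; eigencomponents whose weight e^{−t(1−λ)} has
decayed below 1e−16 relative are dropped, which is exact to machine
precision and makes large-t evaluations cheap.

At each of 100 Markov times on a log₁₀ grid over [−1, 4], MS is maximized
by a generalized Louvain routine operating on the (signed, dense) quality
matrix Q(t) = sym(P(t) − 1πᵀ), whose same-community sum equals MS(t)
exactly.  Standard Louvain implementations only optimize graph modularity,
so the local-move/aggregation loop is written in-house (numba-compiled);
each run starts from singletons and only accepts strictly improving moves,
so the returned partition is never worse than the singleton baseline.  When
Q(t) has fully equilibrated numerically (max |Q| < 1e−12) every partition
scores ~0 and the routine reports the t → ∞ limit, one spanning community.

An ensemble of Louvain runs per scale (library default 100; the validation
studies use 15, see *Problem sizes*) yields a representative partition
(highest MS, ties to the lowest run index) and the ensemble dispersion
VI_g, the mean pairwise variation of information

    VI(X, Y) = H(X) + H(Y) − 2 I(X; Y)        (natural log),

normalized by R² including the zero diagonal.  Representative partitions
across scales form the matrix VI_P; a **basin** is a maximal contiguous run
of scales whose representatives are pairwise within θ = 0.1 nats of each
other.  Basins at least `basin_min_width` grid points wide (default 3 on
the 100-point grid; both thresholds are CLI-exposed) each contribute one
selected scale — the one minimizing VI_g — ordered coarse → fine by
decreasing Markov time, with duplicate partitions deduplicated.  If no
basin qualifies the global VI_g minimum is returned with a warning.  The
width default was calibrated once on the synthetic hierarchy benchmark: on
a 100-point grid the coarsest (2-cluster) regime of strongly separated
data occupies only the last few grid points, because the planted branches
share almost no expression and merge only at the largest Markov times.
Selected hierarchies are not forced to be strictly nested; a
non-monotone community count across selected scales raises a warning, not
an error.

If the KNN union graph is disconnected (common for well-separated
synthetic clusters), connectivity is repaired before the walk is built:
for every component pair the single highest-cosine bridging edge is a
candidate, and a maximum-spanning tree over components selects which
bridges to add (weights floored at 1e−6 to keep the chain irreducible).
The bridge weights then order the hierarchical merges, so strongly related
components join at smaller Markov times.

## Ligand–receptor specificity over the hierarchy

A unit (possibly multi-subunit, symbols joined by `_`) has per-cell
expression equal to the geometric mean of its subunit columns — any
silent subunit silences the unit.  For every cluster at every selected
scale, each unit is tested one-vs-rest with a one-sided (greater) Wilcoxon
rank-sum test; because the pooled sample is always all cells, the per-gene
ranking is computed once and reused across clusters and scales.  The
normal approximation carries both tie and continuity corrections; when
both groups have ≤ 12 cells an exact tail probability is computed by
dynamic programming over the tied-rank multiset.  Each unit is assigned
globally to the (scale, cluster) with the smallest p-value (ties to the
coarser scale, then the lower cluster id).  A database pair is *specific*
when both sides pass p < 10⁻³ (raw p-values, no multiplicity correction —
a Benjamini–Hochberg option exists but is off by default), and pairs are
ranked ascending by the product of the two p-values.

Interaction strength between cell groups uses a deliberately simple
mass-action saturation: strength = xy / (K_h + xy) with x, y the mean
ligand/receptor unit expression of sender/receiver and K_h = 0.5.  Nothing
downstream depends on the absolute values — only orderings and per-pair
proportions — and any callable (sender cells, receiver cells, pair) → ℝ₊
can be plugged in without changing the detected structures.

## Multiscale similarity

A unit's profile is its mean expression over the clusters of each selected
scale; two profiles are compared by Σ_i w_i · cos(u_i, v_i) with
w_i = 1 / (ln max(T_i, 1) + 1), so coarser scales (larger Markov time T_i)
contribute less.  The clamp at T = 1 keeps weights in (0, 1] — the raw
formula is singular or negative below T = 1 depending on the log base, and
the clamp preserves the intended monotone down-weighting.  LR-pair
similarity adds the ligand-side and receptor-side values; pathway profiles
sum member-unit expression before averaging per cluster.  Grouping applies
a seeded 2-D UMAP to the similarity matrix followed by K-means; for small
item sets the UMAP neighborhood is shrunk to ~n/4 (capped at 15) so
distinct similarity blocks are not mixed.  Tests assert only group
recovery on planted blocks, never coordinates.

## Local hierarchy: support trees

The support of a unit is the set of cells with unit expression > τ
(default τ = 0 on raw counts); units supported by fewer than `min_cells`
(default 10) cells are dropped, and units with identical supports merge
into one node (labels joined by `=`).  Two supports are *disjoint* when
their overlap is ≤ ε·m and *inclusive* when it is ≥ (1−ε)·m with unequal
sizes, where m is the smaller support size (ε = 0 by default, giving exact
set relations).  Units whose supports are pairwise disjoint-or-inclusive
form a laminar family — equivalently a forest under inclusion — and the
maximal such families are exactly the maximal cliques of the
disjoint-or-inclusive relation graph, enumerated by Bron–Kerbosch with
pivoting.  Each clique is decomposed into rooted trees by the Hasse
construction (parent = smallest strict superset); connected components are
emitted separately and components below `min_nodes` (default 2) are
filtered.  With ε > 0 laminarity can break transitively; offending
siblings are detached into their own components with a warning.  Trees are
exported as nested JSON and as Newick strings.

Downstream views: entity frequency across trees (descending, ties
alphabetical), ligand-tree × receptor-tree pairing through shared database
interactions, and `lr_union` entities whose support is the union of a
pair's ligand and receptor supports (per database pair).

## Spatial variants

For spot-based data, min-max-scaled coordinates (× weight, default 1.0 —
plain concatenation) are appended to the PCA embedding before graph
construction, which biases the hierarchy toward spatially coherent
clusters.  For tree detection, a unit's support is restricted to spots
with at least one neighbor (Euclidean radius r; default twice the 5th
percentile of nearest-neighbor distances) supporting a cognate partner
unit; the restriction is contractive and monotone in r.  Spatial coherence
of a labeling is scored by a per-label z-score of same-label neighbor
pairs against seeded label permutations (default 200); labels with under
two cells, or degenerate permutation variance, report NaN.

## Synthetic validation data

**Hierarchy study.**  1000 cells × 10,000 genes with three perfectly
nested balanced labelings of 2 / 4 / 8 clusters.  1000 genes are markers:
200 per cluster at the coarsest scale, 100 at the middle, 25 at the finest
(per-scale totals 400 / 400 / 200).  Counts are negative binomial with
variance μ + 0.1 μ² (dispersion 0.1).  A marker's in/out-cluster means
satisfy μ_in = FC · μ_out with the population mean conserved at the gene's
base mean (μ_out = μ_base / (f·FC + 1 − f), f the cluster fraction).  The
`builtin` parameter profile draws a pool of 13,714 gene means from
log-normal(μ=1, σ=1), takes marker base means from the top-20% stratum and
background means from the lower 80%, with per-scale fold changes
(3, 4, 5); it is a documented emulation of parameters derived from a
public PBMC reference, not that dataset itself.  The `pbmc3k` mode derives
both strata and the fold changes from a locally downloaded 10x PBMC-3k
matrix (median-normalization, 80th-percentile split, median one-vs-rest
fold change of the top 400/400/200 DE genes over a coarse k-means
clustering).  The generator does not emulate doublets, ambient RNA, batch
effects or library-size variation, so passing benchmarks demonstrate
correctness of the machinery on idealized NB data, not robustness to those
artifacts.

**Tree study.**  1000 cells × 100 binary genes.  15 structured genes
realize five planted trees (two 3-node chains and three root-with-two-
disjoint-children tops) on mutually disjoint 180-cell root blocks assigned
through a seeded permutation; children occupy disjoint splits of 80% of
their parent's cells so inclusions are strict.  Each of the 85 background
genes is expressed in 500 uniformly drawn cells, re-drawn per seed; such
supports are overwhelmingly in partial overlap with everything, so they
join no tree.

**Evaluation.**  ARI (permutation-model adjusted Rand index) between
selected and planted partitions, with each planted scale matched to the
selected scale of maximal ARI; marker recovery = the fraction of the top-N
lowest-p genes that are planted markers assigned to the matching
(scale, cluster), with truth clusters mapped to detected clusters by
Hungarian assignment on the overlap contingency; tree recovery = exact
match of a detected tree's entity set and parent map to a planted
topology.

## Problem sizes and reproducibility

The validation studies (test suite and `scripts/acceptance.py`) run the
generators at the full study sizes above but use a scan profile of 100
grid points × 15 Louvain runs per scale; the Louvain ensemble size mainly
sharpens the VI_g diagnostic, and 15 runs is ample on these benchmarks
while keeping five replicate studies desk-sized.  All randomness flows
from explicit seeds (a master seed spawns per-scale and per-run seeds via
`numpy.random.SeedSequence`), and identical (config, seed) reruns produce
byte-identical cluster TSV and tree JSON outputs.

## Known limitations

* The MS quality matrix is dense; the exact spectral route is intended for
  graphs up to a few thousand cells (matching the 3000-cell subsamples the
  hierarchy analyses are designed around).  A linearized I − tL fallback
  for larger graphs is possible behind the same interface but not enabled.
* Scale selection reports basins as-is; it does not enforce nestedness
  across scales.
* The CCC score is a stand-in with a pluggable interface; it implements no
  cofactors, trimean aggregation, permutation significance, or spatial
  optimal transport.
* Tree detection is hard-threshold: no probabilistic support membership,
  and results at ε > 0 depend on a greedy laminarity repair.
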