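# Methods

This note documents the models, the numerical choices, and what the test
suite does and does not establish.

## Preprocessing

Counts are filtered once, genes before cells: genes detected (count > 0) in
fewer than 10 cells are removed, then cells with fewer than 500 UMIs
(boundaries inclusive at the thresholds). Optionally ADT features and RNA
features whose identifier contains a period are dropped. Three matrices are
derived from the filtered counts:

* `X^raw` — counts on the top overdispersed genes (default 2,000), each
  gene divided by its standard deviation, no centering, clipped at the
  99.99th-percentile value computed over all entries of the scaled matrix.
* `X^norm` — per-cell TP10K (computed on the full filtered gene set, before
  gene subsetting), then the same gene subset and per-gene unit-variance
  scaling. Used only to build the PCs that drive batch soft-clustering.
* `TPM` — per-cell TP10K over all retained features, with the RNA and ADT
  blocks normalized to 10,000 separately, used for the final spectra refit.

All standard deviations in this package are population SDs (ddof 0); one
convention, asserted in tests.

Overdispersed genes are ranked by the vst statistic: a lowess trend (frac
0.3, locally linear) of log10 variance against log10 mean gives each gene a
regularized SD; counts are standardized by it, clipped at sqrt(N), and
genes are ranked by the variance of the clipped values. The locally linear
lowess is this package's dialect of the published degree-2 loess trend; on
the simulations used here the two rankings agree closely at the top of the
list, which is all the pipeline consumes.

ADT proteins for manual gating are TP10K-normalized, CLR-transformed per
cell on pseudocounted values (log(x+1) minus the per-cell mean of logs — a
per-cell geometric-mean CLR, chosen because the compositional constraint
acts within a cell), scaled to unit variance per protein, clipped at 15,
embedded by PCA, batch-corrected, and smoothed by a kNN diffusion operator:
directed k=5 edges symmetrized by union, self-loops added, rows normalized,
and the operator powered to t=3 applied to the scaled protein matrix. A
constant protein column is a fixed point of the operator; increasing t
monotonically contracts within-cluster variance.

## Batch correction

Soft clusters are learned on PCs of `X^norm` by diversity-penalized soft
k-means in cosine geometry: responsibilities are proportional to
`exp(-d²/σ) · Π_b ((E+1)/(O+1))^θ`, where O and E are observed and expected
cluster-by-batch co-occurrences, updated over randomized 5% blocks;
centroids are responsibility-weighted means re-projected to the unit
sphere. Defaults: σ = 0.1, θ = 2 per covariate, 50 PCs, `n_clusters =
min(100, round(n/30))`; convergence when the relative objective change
drops below 1e-4. A single batch level zeroes θ and reduces the procedure
to plain soft k-means.

The correction is a per-cluster mixture-of-experts linear model fit by
responsibility-weighted ridge regression of gene values on an intercept
plus batch indicators (ridge λ = 1 on the batch columns, 0 on the
intercept). Only the batch component is subtracted — the intercept, i.e.
the cluster's own expression, is kept — and, deviating from the standard
embedding-level correction, the target is the gene-level `X^raw`. This
creates small negative values around zero, so the result is floored at 0
once, at the end; the floored fraction is reported so users can monitor it.
With a single batch level the design would be collinear (the intercept
equals the only indicator), so the correction subtracts nothing.

## Consensus NMF

Per k, `n_iter` NMF factorizations (Frobenius objective, multiplicative
updates, tol 1e-4, max 1,000 iterations, seeded random initializations) are
combined: replicate spectra are L2-normalized; each component's mean
distance to its `int(local_neighborhood_size · n_iter)` nearest neighbors
is computed in squared Euclidean distance (= 2 − 2·cosine, whose maximum
for nonnegative unit vectors is 2, so a threshold of 2 disables the
filter); components above `density_threshold` (default 0.15) are dropped;
survivors are k-means clustered (seeded, n_init 10) into k clusters and the
per-cluster medians, re-normalized to unit L2, are the consensus spectra.
Usages are refit against them by NNLS, stability is the silhouette of the
clustered components, and the reconstruction error is the relative
Frobenius residual. The choice of k is never made silently: `cnmf scan`
prints the stability/error table and `cnmf finalize` requires `--k-final`
(a helper suggests the largest k within 90% of the maximum stability).

Final spectra are refit over all retained features: `spectra_tpm` by NNLS
of the TPM matrix on the usages, rows renormalized to 1e6; `spectra_zscore`
by ordinary least squares of per-feature standardized TPM on the usages,
giving marker-gene weights in z units.

## Catalog merging

Dataset spectra (TPM units) are renormalized to sum to 1e6 and divided
gene-wise by that dataset's TP10K SD (zero-SD genes dropped from the
vector). Edges require (1) different datasets, (2) Pearson R > 0.5 computed
on the union of the two datasets' overdispersed genes restricted to genes
both vectors carry (pairs sharing fewer than 20 genes get no edge), and
(3) mutual membership in each other's top-7 correlations, ranked over all
other nodes with ties broken by node index. The greedy merge makes a single
pass over edges in decreasing R (ties broken lexicographically by
(dataset, name)); a merge is accepted when at least two-thirds of all
unordered node pairs in the candidate union are connected — counting all
pairs, not only newly formed ones. Failed merges are not retried. The
catalog universe is the union of per-dataset overdispersed genes
intersected with every dataset's full gene list; merged sets (and
explicitly named singletons) are averaged element-wise on it, with genes a
member lacks averaged over the members that carry them.

## Fixed-catalog projection and scores

The query is subset to the genes shared with the catalog (floor: 20), each
gene divided by its SD across query cells computed on raw counts (a config
switch computes it on TP10K instead); no centering and no ceiling. Usages
solve the convex per-cell NNLS against the fixed spectra. The default
optimizer is coordinate descent at tol 1e-10, which reaches the unique
optimum (it matches an independent active-set solver to ~1e-8 per entry);
the slower multiplicative-update variant used by some published pipelines
is available via `solver="mu"`. Usage rows are normalized to sum to 1;
cells whose raw usage is all ~0 are reported and left at zero, never
silently renormalized. Because the per-gene SDs are fixed by the query,
scaling one cell's counts by any positive constant leaves its normalized
usage unchanged.

Scores are sums of named usage components with strict ">" thresholds: ASA
(default threshold 0.0625; 0.065 — used by some published figure panels —
is available as a parameter), cell cycle (0.1), and doublet flags (0.1 over
doublet-class programs; this threshold has no published value and is
config-exposed). The subset classifier standardizes usages to zero mean and
unit variance and fits a multinomial logistic regression (lbfgs, L2,
`class_weight="balanced"` so each subset contributes equally regardless of
size). Balanced accuracy is implemented as the mean per-class recall.

## The scsim2 simulator

The count model is gamma-Poisson: baseline gene means are
Gamma(shape 0.34, rate 7.68) with probability 0.00286 of being replaced by
`median · LogNormal(6.15, 0.49)`; library sizes are LogNormal(7.64, 0.78)
(median ≈ 2,079 UMIs); per GEP each gene is up-regulated with probability
0.025 by LogNormal(1, 1) or down-regulated with probability 0.025 by its
reciprocal. Each cell draws one subset GEP uniformly; each activity GEP
switches on independently with probability 0.3 and draws a usage uniform
in (0.1, 0.7); if total activity exceeds 0.8 it is rescaled to exactly 0.8,
so subset usage never falls below 0.2. A cell's mean profile is the
baseline means times the usage-weighted arithmetic mixture of GEP factor
vectors (the mixing rule is isolated in one function so it can be swapped),
rescaled to the library size before dispersion; per entry the BCV
`b = (0.448 + 1/sqrt(mean)) · sqrt(22.087/χ²)` inflates a Gamma mean that a
Poisson count is drawn from. Counts are generated in cell chunks and stored
sparse. Usage rows are compensated to sum to 1 to within one floating-point
ulp.

The benchmark builder draws one shared 20-GEP/10,000-gene universe and
simulates an extra-GEP reference (all 20 GEPs), a missing-GEP reference
(6+6) and a query (8+8) with nested GEP sets, each on an independent
9,000-gene subset. What the simulator does **not** emulate: batch effects,
ambient RNA, doublets, dropout beyond the gamma-Poisson model, or gene-gene
correlation beyond shared programs — so green tests show the algorithms
recover the model they assume, not that they are robust to artifacts absent
from the model.

## Benchmark harness and problem sizes

The projection benchmark runs at 10% of the published scale by default:
10,000-cell references, a 2,000-cell query, consensus NMF with 1,000
overdispersed genes, 20 replicates, `local_neighborhood_size` 0.3,
`density_threshold` 0.15, k = 20/12. Learned components are labeled by
Hungarian matching of row-normalized usages against the reference ground
truth (usages are compositional; matching raw usages would be confounded by
library size). The catalog is the TPM-refit spectra over all genes,
renormalized to 1e6 and divided by TP10K SD — the same construction used
for real catalogs. Across seeds this yields mean usage correlations of
roughly 0.78–0.85 for shared GEPs, and reference-only GEPs receive lower
mean usage than shared ones.

At these desk sizes the identifiability limit is visible: with many
programs and few cells the NMF global optimum can genuinely beat the true
factorization, blending one component. The parameter-recovery test
therefore uses a 2,000-cell sample of 6 identity programs over 5,000 genes
(500 overdispersed genes, k = 6), where consensus spectra match the true
profiles at mean Pearson R ≈ 0.9 robustly across seeds; the effect sizes
(DE probability and factor distribution) are always the published values.

## Statistics

Associations are ordinary least squares on pseudobulk mean usages with
Benjamini–Hochberg correction (the independence variant) applied per term
across programs. The AIM design uses an intercept, a stimulated-vs-mock
dummy and a stimulated-and-AIM-positive dummy; positive significant
coefficients classify programs as milieu- or AIM-associated. The disease
design dummy-codes categorical covariates (one level dropped) and can drop
duplicate donors, keeping the sample with more cells. Proliferation uses a
two-tailed paired t-test of per-sample mean usage in high (> 0.1) vs low
cell-cycle cells, requiring ≥ 10 high and ≥ 100 low cells per sample, with
Fisher's method (−2Σlog p ~ χ²(2k)) across datasets. Forward ASA selection
greedily adds the component maximizing mean AUC (Mann–Whitney, midrank
ties) across datasets, stops when the best candidate reduces AUC in every
dataset, and — where neither the add nor the stop condition is decisive —
adds only if the mean improves; under pure noise this policy can admit a
few components but the score stays at chance, which is what the tests
assert. Marker enrichment thresholds z scores at 0.015 and reports the
sample odds ratio ad/bc (infinite when bc = 0) with the two-sided Fisher
exact p.

## Known limitations

* The lowess-based vst trend and the per-cell CLR are documented dialects;
  other implementations differ in detail.
* The soft-clustering correction is evaluated on simulated shifts; no real
  multi-batch dataset ships with the package.
* The greedy merge is order-dependent by construction (that is its
  definition); determinism is guaranteed by explicit tie-breaks, not by
  order-independence.
* Spectra learned from few cells under-determine programs with small,
  partially-used effects; the benchmark quantifies this at 10% scale rather
  than hiding it.
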