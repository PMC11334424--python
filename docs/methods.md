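# Methods

## Data model and preprocessing

The pipeline operates on a sample x KO matrix of estimated gene copies
(read-coverage-weighted counts of all genes annotated with each KO) plus
per-sample metadata. Samples are retained when they have no data-use
restriction, strictly more than 100,000 assembled genes, strictly more
than 30% of genes KO-annotated, gene-copy data available, and a single
read library (no combined assemblies). Thresholds are strict inequalities
read literally; a missing metadata value fails its criterion rather than
defaulting to a pass. Ecosystem labels use the fine-grained ecosystem-type
field when strictly more than 100 samples share it, falling back to the
broader ecosystem field (both missing → "Unclassified") so that no label
describes only a handful of samples.

KOs present in fewer than 10% of samples are removed (a KO at exactly the
threshold is kept; "presence" means a strictly positive count). Filtering
precedes normalization, so the CLR geometric mean runs over the retained
KOs only.

### CLR normalization

Counts are compositional: each sample's total reflects sequencing depth,
not biology. We use the per-sample centered log-ratio transform in log
base 2 with a constant pseudocount prior:

    clr(x)_j = log2(x_j + c) − mean_k log2(x_k + c)

The default prior c = 0.5 is the uniform prior commonly used for
point-estimate CLR of count data; it is configurable, and c = 0 is allowed
for strictly positive matrices (where the transform is exactly invariant
to per-sample rescaling). This is the deterministic point-estimate CLR: a
Monte-Carlo Dirichlet treatment of the counts would give a distribution of
CLR values per cell, but all downstream statistics here consume a single
normalized value per KO per sample, so the point estimate is the right
primitive. Rows are re-centered after the transform so the per-sample mean
is 0 to well below 1e−9.

## Clustering and model selection

Distances are Euclidean in full CLR space (a configuration switch can
first project to PCA scores; full space is the default because the marker
statistics are defined there too). Two partitioning methods are offered:

* **k-means** — Lloyd's algorithm with k-means++ seeding, best of
  `n_init = 10` restarts by within-cluster sum of squares (WCSS),
  deterministic given a seed. The implementation asserts that WCSS never
  increases across Lloyd iterations; if a cluster empties, it is re-seeded
  at the point currently farthest from its assigned centroid (each point
  can be claimed at most once per iteration, and the monotonicity baseline
  restarts after a repair, since a repair may raise the objective).
* **Ward** — agglomerative minimum-variance clustering (Lance–Williams
  update on squared Euclidean distance) via scipy's linkage, cut at k.

**Bootstrap model selection.** For each candidate (method, k), the data
are subsampled B = 100 times (default) without replacement at fraction
0.8 and re-clustered. Each replicate records (i) its mean silhouette on
the subsample and (ii) its ARI against a reference model fitted once on
the full data, restricted to the subsample's members. The reference-fit
comparison was a genuinely open design point; comparing every replicate to
a fixed full-data consensus is simple, reproducible, and measures exactly
the stability one cares about. The winner maximizes mean silhouette, ties
broken by higher mean ARI, then smaller k (parsimony), then method order.
Whether the subsample is drawn with or without replacement was also open;
without replacement avoids duplicate points, which silhouette handles
poorly. Singleton clusters score silhouette 0; a partition of all
singletons scores 0 overall.

**Final model.** To limit overfitting, the production k-means model is
trained on a seeded random half of the samples (`holdout_fraction` is the
*training* fraction; 1.0 reduces to a plain fit) and every sample is then
assigned to its nearest centroid — the natural k-means predict rule.
Sub-clustering subsets the samples of each cluster and re-runs k-means
with `k_sub = 2` inside it.

PCA projection (for the 5-component reduction that precedes nonlinear
embeddings) uses centered SVD scores with the deterministic sign
convention that each component's largest-magnitude loading is positive.

## Marker KOs

For every KO, a Kruskal-Wallis H test (mid-ranks, tie-corrected, p from
the chi-square approximation with k−1 df) is computed across clusters,
followed by Dunn's post-hoc z tests on joint mid-ranks:

    z_ij = (R̄_i − R̄_j) / sqrt([N(N+1)/12 − ΣT/(12(N−1))] (1/n_i + 1/n_j))

with T = t³−t summed over tie groups; two-sided normal p-values are
Bonferroni-multiplied by the k(k−1)/2 pairs (capped at 1). The Bonferroni
scope is per KO across its pairs — matching standard post-hoc practice —
while multiplicity *across* KOs is controlled by the permutation estimate
below. If all observations are tied, the degenerate tests report
(H, p) = (0, 1) and (z, p) = (0, 1).

A KO is a **marker** of cluster c iff every Dunn pair involving c has
corrected p < alpha (default 0.001) and the median log2 fold-change of c
over every other cluster exceeds `min_lfc` (default 2). Because CLR values
are already log2, a difference of CLR values is a log2 fold-change; the
default fold-change statistic is the difference of cluster medians (the
convention of mainstream marker-gene toolkits). The alternative — the
median of all pairwise differences — is available via
`lfc_mode="median_of_differences"`. A fold-change > 0 cannot hold in both
directions, so a KO is the marker of at most one cluster by construction.
The Kruskal-Wallis p is reported but does not enter the marker rule, which
uses only the Dunn p-values and fold-changes.

**Permutation FDR.** Cluster labels are shuffled (preserving cluster
sizes) `n_perm = 100` times and the full criterion re-run; the estimate is
mean(false positives)/max(observed markers, 1), with a flag when no
markers were observed. Ranks and tie corrections are independent of the
labeling, so they are computed once and reused across permutations.

Markers map to pathways through a KO→pathway table (canonical 4-column
TSV or KEGG's 2-column link dialect); a KO in several pathways counts once
per pathway, unmapped markers are tallied separately, and per-category
rollups count each marker once per category. "Top" markers per cluster
are ranked by the minimum over other clusters of the median log2
fold-change (worst-case specificity), ties by H then KO id.

## GC content and taxonomy

GC content is the assembled-metagenome aggregate from sample metadata, a
fraction in [0, 1] (slopes are in CLR units per GC fraction; regressing on
a percentage would scale them by 1/100). Cluster differences in GC or in
per-sample domain proportions (contig counts divided by the sample total;
zero-total samples dropped with a warning) reuse the Kruskal-Wallis + Dunn
machinery. Per-KO association with GC is simple OLS; goodness of fit is
Pearson's r and significance the Wald test t = r·sqrt((n−2)/(1−r²)) with
n−2 df, identical to the slope's t test. Constant-abundance KOs report
r = 0, p = 1; constant GC is an error. The regression pools all
QC-passing samples (a per-cluster stratified mode exists behind a flag);
Bonferroni-adjusted p-values across KOs are reported alongside the raw
ones.

## Synthetic data

The generator emulates the assumed data structure, not biology. Per-KO
base log2 abundances are Normal(0, 2); markers of cluster c add
`marker_delta` (default 4) log2 units in their cluster; GC-linked KOs add
`±gc_beta·(gc_i − mean gc)` with alternating signs (default |slope| 8 CLR
units per GC fraction, 20 KOs). GC is Normal per cluster with means
(0.62, 0.45, 0.45) and sd 0.03 — one high-GC cluster, two lower — and the
default third cluster trades bacterial for archaeal contigs (11% vs 1%)
in the multinomial taxonomy draw (10,000 contigs/sample). Expected
compositions are closed to a log-normal per-sample depth (2^Normal(17,
0.5), about 130k counts) and counts drawn Poisson; an optional Gamma
mixing parameter adds overdispersion. Because the pipeline's statistics
are rank- and CLR-based, Poisson noise suffices and keeps planted CLR
effect sizes interpretable: markers are a small share of total abundance,
so the realized CLR shift approximates `marker_delta` (verified to a bias
below 0.2 at the defaults). Metadata passes QC by default; ecosystem
strings ("Soil-like", "Aquatic-like", "Anaerobic-like") are labels only.

What the generator does **not** emulate: phylogenetic correlation between
KOs, genome-size effects, assembly/annotation bias, structured zero
inflation, or any real covariance between functions. Passing tests
therefore demonstrate that the pipeline recovers the structure it assumes,
not that real metagenomes satisfy those assumptions.

The default scenario (3 clusters x 60 samples, 2000 KOs, 10 markers per
cluster at delta 4) is the reference condition for the recovery checks.
Repeated experiments (cluster-number recovery over 100 seeds, power curves
over effect sizes, null calibration over 50 seeds) run on proportionally
reduced instances — 250 KOs, 30 samples per cluster, B = 10 bootstrap
replicates, scan k = 2..5 — chosen as the smallest sizes at which the
planted structure is still unambiguous; effect sizes are never changed.

## Numerical choices and edge cases

* QC thresholds strict (">"), prevalence inclusive ("removed if < 10%").
* CLR rows are re-centered post-transform; the row-mean contract is 1e−9.
* k-means: k-means++ with probability ∝ D²; convergence when the squared
  centroid shift ≤ 1e−6 or the objective stalls; inertia ties across
  restarts keep the first-seen optimum.
* Selection tie-break order: silhouette, ARI, smaller k, method order.
* ARI is defined as 1 when both partitions are all singletons or both a
  single cluster (agreement is perfect in either case).
* File round-trips are exact: floats are written at full precision and
  parsed with correct rounding.
* Identifiers are opaque strings; KO-looking patterns are not enforced, so
  other ortholog schemes can reuse the pipeline.
* Pipeline stage seeds derive from a stable 4-byte BLAKE2b hash of
  (master seed, stage name), keeping stages decoupled; all seeds stay
  below 2^31.

## Known limitations

* Marker calling needs ≥ 2 samples per cluster and ≥ 2 clusters; the
  chi-square and normal approximations are poor for very small groups.
* The permutation FDR estimates the rate for the criterion as a whole,
  not per-KO q-values.
* The bootstrap ARI measures stability against a full-data reference, not
  against an external truth; on structureless data it degrades with k,
  which is informative but not a significance test.
* GC regression is correlational; no phylogenetic or genome-size
  correction is attempted.
* No BIOM/HDF5 containers, no live database retrieval, no plotting:
  tables in, tables out.
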