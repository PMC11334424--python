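# kofunclust

Functional clustering of metagenomes from KEGG-ortholog (KO) abundance
profiles.

Large metagenome compilations (thousands of samples from soils, oceans,
freshwater, digestors, gut, ...) can be compared through a simple,
low-dimensional representation: the per-sample abundance of each KO, i.e.
the estimated gene copies of every function annotated in the assembly. This
package provides a tested, reusable pipeline that

1. applies metadata quality filters to a sample x KO count table and
   derives per-sample ecosystem labels,
2. normalizes the compositional counts per sample with the centered
   log-ratio transform in log base 2,
   `clr(x)_j = log2(x_j + c) − mean_k log2(x_k + c)`,
   so 0 means "equal to the sample's geometric mean abundance",
3. clusters the normalized profiles (k-means and Ward on Euclidean
   distance), choosing the cluster number k by a bootstrap protocol scored
   with the mean silhouette `s(i) = (b_i − a_i)/max(a_i, b_i)` and the
   adjusted Rand index (ARI) against a full-data reference fit, and fits
   the final k-means model on a random half of the samples to limit
   overfitting,
4. identifies cluster-specific **marker KOs**: a KO is a marker of cluster
   c when every Dunn's post-hoc test (following a Kruskal-Wallis H test
   across clusters) involving c has Bonferroni-corrected p < 0.001 *and*
   its median log2 fold-change over every other cluster exceeds 2; the
   false-discovery rate of this composite rule is estimated by re-running
   it under label permutations,
5. relates clusters to assembled GC content and domain-level taxonomy
   (Kruskal-Wallis + Dunn), and regresses each KO's CLR abundance on GC
   content (OLS; Pearson r; Wald t test with n−2 df).

A fully seeded synthetic-data generator plants known structure — ecosystem
clusters, marker KOs with controlled log2 effects, a GC covariate with
cluster-dependent means, GC-linked KOs, an archaea-enriched cluster — so
every stage can be validated against ground truth.

## Worked example

```python
import numpy as np
from kofunclust import synthetic_data as sd, preprocess as pp, \
    cluster_engine as ce, marker_analysis as ma

spec = sd.ScenarioSpec(n_kos=300, samples_per_cluster=(30, 30, 30), seed=11)
counts, samples, pathways, taxonomy, truth = sd.generate(spec)
norm = pp.clr_normalize(pp.filter_rare_kos(counts))

report = ce.bootstrap_select(norm, range(2, 6), B=20, seed=0)
print("selected:", report.chosen_method, "k =", report.chosen_k)

model = ce.fit_final(norm, k=report.chosen_k, seed=1)
print("ARI vs planted clusters:",
      ce.adjusted_rand(model.labels, truth.labels(norm.sample_ids)))

table = ma.call_markers(norm, model.labels)
print("markers per cluster:", table.marker_counts())

fdr = ma.permutation_fdr(norm, model.labels, ma.MarkerCriterion(n_perm=100), seed=2)
print("permutation FDR estimate:", fdr.fdr_estimate)
```

prints

```
selected: kmeans k = 3
ARI vs planted clusters: 1.0
markers per cluster: {0: 10, 1: 10, 2: 10}
permutation FDR estimate: 0.0
```

The bootstrap chose the planted number of clusters (3), the half-sample
k-means model assigned every sample — including held-out ones — to its
planted cluster (ARI 1.0), the composite criterion recovered exactly the
10 planted markers per cluster, and 100 label permutations produced no
false positives (estimated FDR 0).

## Command line

```sh
kofunclust simulate --spec scenario.yaml --out data/        # planted fixture
kofunclust run-all --config config.yaml                     # full pipeline
kofunclust select-k --config config.yaml                    # single stage
```

`run-all` executes qc → labels → filter → normalize → select-k → fit →
markers → subcluster → gc → taxa. Every stage writes its result table plus
a provenance JSON (parameters, derived seed, input hashes); completed
stages are skipped on re-run, so runs are resumable. One master seed
deterministically derives all stage seeds.

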