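"""Synthetic metagenome KO-profile generator with planted structure.

The generator emulates the data shape the pipeline assumes: a compositional
count matrix over k latent ecosystem clusters, with

* per-KO base abundances drawn log-normally (``mu_j ~ Normal`` on log2),
* cluster-specific marker KOs shifted by ``marker_delta`` log2 units in
  their cluster (so the planted CLR-scale effect ~ ``marker_delta`` as long
  as markers are a small share of total abundance),
* a per-sample GC-content covariate with cluster-dependent mean, and a set
  of GC-linked KOs whose log2 abundance tracks GC with slope ``+-gc_beta``
  (alternating signs),
* per-sample sequencing depth drawn log-normally; expected compositions are
  closed to that depth and counts drawn Poisson (optionally Gamma-mixed for
  overdispersion),
* pass-by-default QC metadata, per-cluster ecosystem labels, a small
  pathway map that places each cluster's markers in a dedicated planted
  pathway, and per-sample domain-level taxonomy counts with one optionally
  archaea-enriched cluster.

Every draw flows from a single seed; regeneration is byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .profiles_io import (
    CountMatrix,
    PathwayMap,
    SampleTable,
    TaxonomyTable,
    write_count_matrix,
    write_pathway_map,
    write_sample_table,
    write_taxonomy_table,
)

__all__ = ["ScenarioSpec", "GroundTruth", "generate", "generate_null", "write_fixture"]


@dataclass(frozen=True)
class ScenarioSpec:
    """Parameters of a planted-structure scenario.

    Defaults describe the reference scenario: 3 ecosystem clusters of 60
    samples, 2000 KOs, 10 markers per cluster at a log2 effect of 4, GC
    means 0.62/0.45/0.45 (sd 0.03), 20 GC-linked KOs at |slope| 8 CLR units
    per GC fraction, and an archaea-enriched third cluster.
    """

    n_clusters: int = 3
    samples_per_cluster: tuple = (60, 60, 60)
    n_kos: int = 2000
    markers_per_cluster: int = 10
    marker_delta: float = 4.0
    baseline_logmean: float = 0.0
    baseline_sd: float = 2.0
    depth_logmean: float = 17.0   # log2 of expected total counts (~130k)
    depth_sd: float = 0.5
    gc_means: tuple = (0.62, 0.45, 0.45)
    gc_sd: float = 0.03
    n_gc_linked_kos: int = 20
    gc_beta: float = 8.0
    archaea_rich_cluster: int | None = 2
    contigs_per_sample: int = 10_000
    overdispersion: float = 0.0   # Gamma mixing variance; 0 = pure Poisson
    seed: int = 0

    def validate(self) -> None:
        if self.n_clusters < 1:
            raise ValueError("n_clusters must be >= 1")
        if len(self.samples_per_cluster) != self.n_clusters:
            raise ValueError("samples_per_cluster length must equal n_clusters")
        if any(s < 1 for s in self.samples_per_cluster):
            raise ValueError("every cluster needs at least 1 sample")
        planted = self.markers_per_cluster * self.n_clusters + self.n_gc_linked_kos
        if planted > self.n_kos:
            raise ValueError(
                f"{planted} planted KOs exceed the {self.n_kos} available"
            )
        if len(self.gc_means) != self.n_clusters:
            raise ValueError("gc_means length must equal n_clusters")
        if any(not 0 < g < 1 for g in self.gc_means):
            raise ValueError("gc_means must lie in (0, 1)")
        if self.baseline_sd <= 0 or self.depth_sd <= 0 or self.gc_sd <= 0:
            raise ValueError("scale parameters must be positive")
        if self.archaea_rich_cluster is not None and not (
            0 <= self.archaea_rich_cluster < self.n_clusters
        ):
            raise ValueError("archaea_rich_cluster out of range")
        if self.overdispersion < 0:
            raise ValueError("overdispersion must be >= 0")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["samples_per_cluster"] = list(self.samples_per_cluster)
        d["gc_means"] = list(self.gc_means)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioSpec":
        d = dict(d)
        unknown = set(d) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown scenario keys: {sorted(unknown)}")
        for key in ("samples_per_cluster", "gc_means"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class GroundTruth:
    """Everything planted: cluster memberships, marker sets, GC-linked KOs."""

    cluster_of: dict        # sample_id -> cluster index
    markers: dict           # cluster index -> [ko_id]
    gc_linked: dict         # ko_id -> signed slope on the log2 scale
    gc_means: list
    archaea_rich_cluster: int | None
    seed: int

    def labels(self, sample_ids) -> np.ndarray:
        return np.array([self.cluster_of[s] for s in sample_ids], dtype=int)

    def all_marker_kos(self) -> set:
        return {ko for kos in self.markers.values() for ko in kos}

    def to_json(self, path: str | Path) -> None:
        payload = {
            "cluster_of": self.cluster_of,
            "markers": {str(c): kos for c, kos in self.markers.items()},
            "gc_linked": self.gc_linked,
            "gc_means": list(self.gc_means),
            "archaea_rich_cluster": self.archaea_rich_cluster,
            "seed": self.seed,
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        d = json.loads(Path(path).read_text())
        return cls(
            cluster_of=d["cluster_of"],
            markers={int(c): kos for c, kos in d["markers"].items()},
            gc_linked=d["gc_linked"],
            gc_means=d["gc_means"],
            archaea_rich_cluster=d["archaea_rich_cluster"],
            seed=d["seed"],
        )


_ECOSYSTEM_TYPES = ("Soil-like", "Aquatic-like", "Anaerobic-like")
_ECOSYSTEMS = ("Terrestrial", "Aquatic", "Engineered")

# baseline contig fractions per domain (bacteria-dominated, as in real
# assemblies); the archaea-rich cluster trades bacterial for archaeal contigs
_BASE_TAX = np.array([0.95, 0.01, 0.02, 0.01, 0.01])
_ARCHAEA_TAX = np.array([0.85, 0.11, 0.02, 0.01, 0.01])


def generate(
    spec: ScenarioSpec,
) -> tuple[CountMatrix, SampleTable, PathwayMap, TaxonomyTable, GroundTruth]:
    """Draw one full synthetic study from ``spec`` (deterministic in seed)."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    k, p = spec.n_clusters, spec.n_kos
    n = int(sum(spec.samples_per_cluster))
    labels = np.repeat(np.arange(k), spec.samples_per_cluster)
    sample_ids = [f"S{i:04d}" for i in range(n)]
    ko_ids = [f"K{j + 1:05d}" for j in range(p)]

    # disjoint planted index sets
    perm = rng.permutation(p)
    m = spec.markers_per_cluster
    marker_idx = {c: np.sort(perm[c * m : (c + 1) * m]) for c in range(k)}
    gc_idx = np.sort(perm[k * m : k * m + spec.n_gc_linked_kos])
    gc_signs = np.array([1.0 if i % 2 == 0 else -1.0 for i in range(len(gc_idx))])

    mu = rng.normal(spec.baseline_logmean, spec.baseline_sd, size=p)
    gc = np.clip(
        rng.normal(np.asarray(spec.gc_means)[labels], spec.gc_sd), 0.01, 0.99
    )

    log2_expected = np.tile(mu, (n, 1))
    for c in range(k):
        rows = np.flatnonzero(labels == c)
        log2_expected[np.ix_(rows, marker_idx[c])] += spec.marker_delta
    gc_centered = gc - float(np.mean(spec.gc_means))
    log2_expected[:, gc_idx] += np.outer(gc_centered, gc_signs * spec.gc_beta)

    expected = np.exp2(log2_expected)
    composition = expected / expected.sum(axis=1, keepdims=True)
    depth = np.exp2(rng.normal(spec.depth_logmean, spec.depth_sd, size=n))
    lam = composition * depth[:, None]
    if spec.overdispersion > 0:
        shape = 1.0 / spec.overdispersion
        lam = lam * rng.gamma(shape, scale=1.0 / shape, size=lam.shape)
    counts = rng.poisson(lam).astype(float)
    cm = CountMatrix(sample_ids, ko_ids, counts)

    # metadata passes QC by default
    meta = pd.DataFrame(index=pd.Index(sample_ids, name="sample_id"))
    meta["ecosystem_type"] = [
        _ECOSYSTEM_TYPES[c] if c < len(_ECOSYSTEM_TYPES) else f"Env{c}-like"
        for c in labels
    ]
    meta["ecosystem"] = [
        _ECOSYSTEMS[c] if c < len(_ECOSYSTEMS) else f"Environment {c}"
        for c in labels
    ]
    meta["gc_content"] = gc
    meta["gene_count"] = rng.integers(1_200_000, 1_800_000, size=n)
    meta["pct_ko_annotated"] = np.round(
        np.clip(rng.normal(38.8, 2.0, size=n), 30.5, 60.0), 3
    )
    meta["has_copy_data"] = True
    meta["is_combined_assembly"] = False
    meta["use_restricted"] = False
    samples = SampleTable(meta)

    # pathway map: each cluster's markers share a dedicated planted pathway;
    # every KO may additionally join a generic pathway
    categories = [
        "Energy metabolism",
        "Xenobiotics biodegradation and metabolism",
        "Carbohydrate metabolism",
        "Membrane transport",
        "Translation",
    ]
    entries = set()
    for c in range(k):
        pid = f"map9{c:04d}"
        for j in marker_idx[c]:
            entries.add((ko_ids[j], pid, f"Planted pathway {c}", categories[c % len(categories)]))
    generic = rng.random(p) < 0.5
    generic_choice = rng.integers(0, 10, size=p)
    for j in np.flatnonzero(generic):
        g = int(generic_choice[j])
        entries.add(
            (ko_ids[j], f"map0{g:04d}", f"Generic pathway {g}", categories[g % len(categories)])
        )
    pmap = PathwayMap(entries)

    tax_fracs = np.stack(
        [
            _ARCHAEA_TAX if c == spec.archaea_rich_cluster else _BASE_TAX
            for c in labels
        ]
    )
    tax_counts = np.stack(
        [rng.multinomial(spec.contigs_per_sample, f) for f in tax_fracs]
    )
    tax = TaxonomyTable(
        pd.DataFrame(
            tax_counts,
            index=pd.Index(sample_ids, name="sample_id"),
            columns=["bacteria", "archaea", "eukaryota", "viruses", "unassigned"],
        )
    )

    truth = GroundTruth(
        cluster_of={s: int(c) for s, c in zip(sample_ids, labels)},
        markers={c: [ko_ids[j] for j in marker_idx[c]] for c in range(k)},
        gc_linked={
            ko_ids[j]: float(s * spec.gc_beta) for j, s in zip(gc_idx, gc_signs)
        },
        gc_means=list(spec.gc_means),
        archaea_rich_cluster=spec.archaea_rich_cluster,
        seed=spec.seed,
    )
    return cm, samples, pmap, tax, truth


def generate_null(
    n_samples: int, n_kos: int, seed: int, **overrides
) -> tuple[CountMatrix, SampleTable]:
    """A single-population dataset: no clusters, no planted effects.

    GC content still varies sample-to-sample (independently of every KO), so
    the null behavior of the GC regression can be calibrated.
    """
    if n_samples < 1 or n_kos < 1:
        raise ValueError("sizes must be positive")
    spec = ScenarioSpec(
        n_clusters=1,
        samples_per_cluster=(n_samples,),
        n_kos=n_kos,
        markers_per_cluster=0,
        marker_delta=0.0,
        gc_means=(0.5,),
        gc_sd=0.05,
        n_gc_linked_kos=0,
        gc_beta=0.0,
        archaea_rich_cluster=None,
        seed=seed,
        **overrides,
    )
    cm, samples, _, _, _ = generate(spec)
    return cm, samples


def write_fixture(outdir: str | Path, spec: ScenarioSpec = ScenarioSpec()) -> dict:
    """Write a full scenario to ``outdir`` in the pipeline's on-disk formats.

    Emits counts.tsv, samples.tsv, pathways.tsv, taxonomy.tsv,
    ground_truth.json, and scenario.json (the spec needed to regenerate the
    fixture bit-for-bit). Returns the path map.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cm, samples, pmap, tax, truth = generate(spec)
    paths = {
        "counts": outdir / "counts.tsv",
        "samples": outdir / "samples.tsv",
        "pathways": outdir / "pathways.tsv",
        "taxonomy": outdir / "taxonomy.tsv",
        "ground_truth": outdir / "ground_truth.json",
        "scenario": outdir / "scenario.json",
    }
    write_count_matrix(cm, paths["counts"])
    write_sample_table(samples, paths["samples"])
    write_pathway_map(pmap, paths["pathways"])
    write_taxonomy_table(tax, paths["taxonomy"])
    truth.to_json(paths["ground_truth"])
    paths["scenario"].write_text(json.dumps(spec.to_dict(), indent=1, sort_keys=True))
    return {k: str(v) for k, v in paths.items()}
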