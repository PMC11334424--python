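"""End-to-end orchestration with a flat config, provenance, and resumability.

The pipeline runs: sample QC -> ecosystem labels -> rare-KO filter -> CLR ->
bootstrap model selection -> final half-sample k-means fit -> marker calling
(+ permutation FDR, pathway rollup, top-N) -> sub-clustering -> GC regression
and cluster comparison -> taxonomy comparison. Every stage writes its result
table(s) plus a JSON provenance record (parameters, derived seed, SHA-256 of
its inputs); a completed stage whose parameters are unchanged is skipped on
re-run, so deleting a late stage's outputs and re-running regenerates only
those.

One master seed drives everything; each stage derives its own seed from a
stable hash of (master seed, stage name) so toggling one stage never
perturbs another.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import cluster_engine as ce
from . import covariate_analysis as cov
from . import marker_analysis as ma
from . import preprocess as pp
from . import profiles_io as pio

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "validate_config", "run_all", "run_stage", "STAGES"]


@dataclass
class PipelineConfig:
    """All pipeline inputs and stage parameters in one flat record."""

    counts_path: str = ""
    samples_path: str = ""
    pathways_path: str | None = None
    taxonomy_path: str | None = None
    orientation: str = "samples_as_rows"
    out_dir: str = "run"
    # preprocessing
    min_genes: int = 100_000
    min_pct_annotated: float = 30.0
    min_ecosystem_count: int = 100
    min_prevalence: float = 0.10
    prior: float = 0.5
    # model selection / fitting
    k_min: int = 2
    k_max: int = 6
    bootstrap_B: int = 100
    subsample_fraction: float = 0.8
    methods: tuple = ("kmeans", "ward")
    n_init: int = 10
    k: int | None = None          # overrides the selected k when set
    holdout_fraction: float = 0.5
    k_sub: int = 2
    # marker analysis
    alpha: float = 0.001
    min_lfc: float = 2.0
    n_perm: int = 100
    lfc_mode: str = "difference_of_medians"
    n_top: int = 15
    # covariates
    n_top_gc: int = 20
    seed: int = 0

    def stage_seed(self, stage: str) -> int:
        digest = hashlib.blake2b(
            f"{self.seed}:{stage}".encode(), digest_size=4
        ).digest()
        return int.from_bytes(digest, "big") % (2**31)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["methods"] = list(self.methods)
        return d


_DOMAIN_CHECKS = {
    "orientation": lambda v: v in ("samples_as_rows", "samples_as_cols"),
    "min_genes": lambda v: v >= 0,
    "min_pct_annotated": lambda v: 0 <= v <= 100,
    "min_ecosystem_count": lambda v: v >= 0,
    "min_prevalence": lambda v: 0 <= v <= 1,
    "prior": lambda v: v >= 0,
    "k_min": lambda v: v >= 2,
    "bootstrap_B": lambda v: v >= 2,
    "subsample_fraction": lambda v: 0 < v <= 1,
    "n_init": lambda v: v >= 1,
    "holdout_fraction": lambda v: 0 < v <= 1,
    "k_sub": lambda v: v >= 1,
    "alpha": lambda v: 0 < v < 1,
    "min_lfc": lambda v: v >= 0,
    "n_perm": lambda v: v >= 1,
    "lfc_mode": lambda v: v in ("difference_of_medians", "median_of_differences"),
    "n_top": lambda v: v >= 1,
    "n_top_gc": lambda v: v >= 1,
}


def validate_config(raw: dict) -> PipelineConfig:
    """Type- and domain-check a flat config mapping; fill defaults.

    Unknown keys are rejected by name; out-of-domain values are reported
    with the offending key.
    """
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config key(s): {sorted(unknown)}")
    raw = dict(raw)
    if "methods" in raw:
        raw["methods"] = tuple(raw["methods"])
        if not raw["methods"] or any(
            m not in ("kmeans", "ward") for m in raw["methods"]
        ):
            raise ValueError("config key methods: allowed values are kmeans, ward")
    cfg = PipelineConfig(**raw)
    for key, check in _DOMAIN_CHECKS.items():
        if not check(getattr(cfg, key)):
            raise ValueError(f"config key {key}: value {getattr(cfg, key)!r} out of range")
    if cfg.k_max < cfg.k_min:
        raise ValueError("config key k_max: must be >= k_min")
    if cfg.k is not None and cfg.k < 2:
        raise ValueError("config key k: must be >= 2")
    return cfg


# ----------------------------------------------------------------- stages


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _params_hash(cfg: PipelineConfig) -> str:
    return hashlib.sha256(
        json.dumps(cfg.to_dict(), sort_keys=True).encode()
    ).hexdigest()


def _provenance_path(rundir: Path, stage: str) -> Path:
    return rundir / f"{stage}.provenance.json"


def _stage_done(rundir: Path, stage: str, cfg: PipelineConfig, outputs: list[str]) -> bool:
    prov = _provenance_path(rundir, stage)
    if not prov.exists():
        return False
    try:
        rec = json.loads(prov.read_text())
    except json.JSONDecodeError:
        return False
    if rec.get("params_hash") != _params_hash(cfg):
        return False
    return all((rundir / o).exists() for o in outputs)


def _record(rundir: Path, stage: str, cfg: PipelineConfig, inputs: list[Path], outputs: list[str]) -> None:
    rec = {
        "stage": stage,
        "seed": cfg.stage_seed(stage),
        "params_hash": _params_hash(cfg),
        "inputs": {str(p): _sha256(Path(p)) for p in inputs if Path(p).exists()},
        "outputs": sorted(outputs),
    }
    _provenance_path(rundir, stage).write_text(json.dumps(rec, indent=1, sort_keys=True))


def _read_clr(rundir: Path) -> pp.NormalizedMatrix:
    df = pd.read_csv(rundir / "clr.tsv", sep="\t", index_col=0)
    values = df.to_numpy(dtype=float)
    values = values - values.mean(axis=1, keepdims=True)
    return pp.NormalizedMatrix(
        list(df.index.astype(str)), list(df.columns.astype(str)), values, prior=np.nan
    )


def _read_labels(rundir: Path) -> pd.Series:
    df = pd.read_csv(rundir / "cluster_labels.tsv", sep="\t", index_col=0)
    return df["cluster"]


def _stage_qc(cfg: PipelineConfig, rundir: Path) -> None:
    counts = pio.read_count_matrix(cfg.counts_path, orientation=cfg.orientation)
    samples = pio.read_sample_table(cfg.samples_path)
    kept, report = pp.apply_sample_qc(
        samples, counts, min_genes=cfg.min_genes, min_pct_annotated=cfg.min_pct_annotated
    )
    report.to_tsv(rundir / "qc_report.tsv")
    pio.write_count_matrix(kept, rundir / "counts_qc.tsv")
    logger.info("qc: %d/%d samples retained", report.n_passed, report.n_input)


def _stage_labels(cfg: PipelineConfig, rundir: Path) -> None:
    samples = pio.read_sample_table(cfg.samples_path)
    labeled = pp.assign_ecosystem_labels(samples, min_count=cfg.min_ecosystem_count)
    pio.write_sample_table(labeled, rundir / "samples_labeled.tsv")


def _stage_filter(cfg: PipelineConfig, rundir: Path) -> None:
    counts = pio.read_count_matrix(rundir / "counts_qc.tsv")
    kept = pp.filter_rare_kos(counts, min_prevalence=cfg.min_prevalence)
    pio.write_count_matrix(kept, rundir / "counts_filtered.tsv")
    logger.info("filter: %d/%d KOs retained", kept.n_kos, counts.n_kos)


def _stage_normalize(cfg: PipelineConfig, rundir: Path) -> None:
    counts = pio.read_count_matrix(rundir / "counts_filtered.tsv")
    norm = pp.clr_normalize(counts, prior=cfg.prior)
    norm.to_frame().to_csv(rundir / "clr.tsv", sep="\t", index_label="sample_id")


def _stage_select_k(cfg: PipelineConfig, rundir: Path) -> None:
    norm = _read_clr(rundir)
    report = ce.bootstrap_select(
        norm,
        k_range=range(cfg.k_min, cfg.k_max + 1),
        methods=cfg.methods,
        B=cfg.bootstrap_B,
        subsample_fraction=cfg.subsample_fraction,
        seed=cfg.stage_seed("select_k"),
        n_init=cfg.n_init,
    )
    report.to_frame().to_csv(rundir / "bootstrap_scores.tsv", sep="\t", index=False)
    (rundir / "selected_model.json").write_text(
        json.dumps(
            {"chosen_k": report.chosen_k, "chosen_method": report.chosen_method},
            indent=1,
            sort_keys=True,
        )
    )
    logger.info("select_k: chose %s with k=%d", report.chosen_method, report.chosen_k)


def _stage_fit(cfg: PipelineConfig, rundir: Path) -> None:
    norm = _read_clr(rundir)
    if cfg.k is not None:
        k = cfg.k
    else:
        k = json.loads((rundir / "selected_model.json").read_text())["chosen_k"]
    model = ce.fit_final(
        norm,
        k=k,
        seed=cfg.stage_seed("fit"),
        holdout_fraction=cfg.holdout_fraction,
        n_init=cfg.n_init,
    )
    model.to_frame().to_csv(rundir / "cluster_labels.tsv", sep="\t")
    pd.DataFrame(model.centroids, columns=norm.ko_ids).to_csv(
        rundir / "centroids.tsv", sep="\t", index_label="cluster"
    )
    (rundir / "final_model.json").write_text(
        json.dumps(
            {
                "k": model.k,
                "method": model.method,
                "seed": model.seed,
                "training_sample_ids": model.training_sample_ids,
                "inertia": model.inertia,
            },
            indent=1,
            sort_keys=True,
        )
    )


def _stage_markers(cfg: PipelineConfig, rundir: Path) -> None:
    norm = _read_clr(rundir)
    labels = _read_labels(rundir).reindex(norm.sample_ids).to_numpy()
    criterion = ma.MarkerCriterion(alpha=cfg.alpha, min_lfc=cfg.min_lfc, n_perm=cfg.n_perm)
    table = ma.call_markers(norm, labels, criterion, lfc_mode=cfg.lfc_mode)
    table.to_tsv(rundir / "markers.tsv")
    fdr = ma.permutation_fdr(
        norm, labels, criterion, seed=cfg.stage_seed("markers"), lfc_mode=cfg.lfc_mode
    )
    (rundir / "fdr.json").write_text(
        json.dumps(
            {
                "observed_markers": fdr.observed_markers,
                "fdr_estimate": fdr.fdr_estimate,
                "no_observed_markers": fdr.no_observed_markers,
                "permutation_counts": fdr.permutation_counts.tolist(),
            },
            indent=1,
            sort_keys=True,
        )
    )
    tops = ma.top_markers(table, n=cfg.n_top)
    pd.concat(
        [df.assign(cluster=c) for c, df in tops.items()]
    ).to_csv(rundir / "top_markers.tsv", sep="\t", index_label="ko_id")
    if cfg.pathways_path:
        pmap = pio.read_pathway_map(cfg.pathways_path)
        rollup = ma.map_markers_to_pathways(table, pmap)
        rollup.per_pathway.to_csv(rundir / "pathway_counts.tsv", sep="\t", index=False)
        rollup.per_category.to_csv(rundir / "category_counts.tsv", sep="\t", index=False)
    logger.info(
        "markers: %d markers, FDR estimate %.4g", table.n_markers, fdr.fdr_estimate
    )


def _stage_subcluster(cfg: PipelineConfig, rundir: Path) -> None:
    norm = _read_clr(rundir)
    labels = _read_labels(rundir).reindex(norm.sample_ids).to_numpy()
    k = int(labels.max()) + 1
    parent = ce.ClusterModel(
        method="kmeans", k=k, labels=labels, sample_ids=norm.sample_ids
    )
    subs = ce.subcluster(norm, parent, k_sub=cfg.k_sub, seed=cfg.stage_seed("subcluster"))
    frames = []
    for c, model in subs.items():
        f = model.to_frame().rename(columns={"cluster": "subcluster"})
        f["cluster"] = c
        frames.append(f)
    pd.concat(frames).to_csv(rundir / "subcluster_labels.tsv", sep="\t")


def _stage_gc(cfg: PipelineConfig, rundir: Path) -> None:
    norm = _read_clr(rundir)
    samples = pio.read_sample_table(rundir / "samples_labeled.tsv")
    gc = samples.column("gc_content").reindex(norm.sample_ids)
    labels = _read_labels(rundir).reindex(norm.sample_ids).to_numpy()
    comparison = cov.compare_across_clusters(gc, labels, variable="gc_content")
    comparison.to_frame().to_csv(rundir / "gc_comparison.tsv", sep="\t", index=False)
    results = cov.gc_ko_regression(norm, gc)
    results.to_csv(rundir / "gc_regression.tsv", sep="\t")
    pos, neg = cov.rank_gc_correlates(results, n_top=cfg.n_top_gc)
    pos.assign(direction="positive").pipe(
        lambda a: pd.concat([a, neg.assign(direction="negative")])
    ).to_csv(rundir / "gc_top_correlates.tsv", sep="\t")


def _stage_taxa(cfg: PipelineConfig, rundir: Path) -> None:
    if not cfg.taxonomy_path:
        (rundir / "taxonomy_comparison.tsv").write_text(
            "variable\tcluster_a\tcluster_b\tH\tkw_p\tdunn_z\tdunn_p\n"
        )
        return
    tax = pio.read_taxonomy_table(cfg.taxonomy_path)
    fractions = cov.taxonomy_proportions(tax)
    labels = _read_labels(rundir)
    shared = [s for s in labels.index if s in fractions.index]
    rows = []
    for domain in pio.TAXONOMY_DOMAINS:
        comp = cov.compare_across_clusters(
            fractions.loc[shared, domain],
            labels.loc[shared].to_numpy(),
            variable=f"fraction_{domain}",
        )
        rows.append(comp.to_frame())
    pd.concat(rows).to_csv(rundir / "taxonomy_comparison.tsv", sep="\t", index=False)


STAGES: dict[str, tuple] = {
    # stage -> (function, output files)
    "qc": (_stage_qc, ["qc_report.tsv", "counts_qc.tsv"]),
    "labels": (_stage_labels, ["samples_labeled.tsv"]),
    "filter": (_stage_filter, ["counts_filtered.tsv"]),
    "normalize": (_stage_normalize, ["clr.tsv"]),
    "select_k": (_stage_select_k, ["bootstrap_scores.tsv", "selected_model.json"]),
    "fit": (_stage_fit, ["cluster_labels.tsv", "centroids.tsv", "final_model.json"]),
    "markers": (_stage_markers, ["markers.tsv", "fdr.json", "top_markers.tsv"]),
    "subcluster": (_stage_subcluster, ["subcluster_labels.tsv"]),
    "gc": (_stage_gc, ["gc_comparison.tsv", "gc_regression.tsv", "gc_top_correlates.tsv"]),
    "taxa": (_stage_taxa, ["taxonomy_comparison.tsv"]),
}


def run_stage(cfg: PipelineConfig, stage: str, force: bool = False) -> None:
    """Run one stage (its inputs must already exist in the run directory)."""
    if stage not in STAGES:
        raise ValueError(f"unknown stage {stage!r}")
    rundir = Path(cfg.out_dir)
    rundir.mkdir(parents=True, exist_ok=True)
    func, outputs = STAGES[stage]
    if not force and _stage_done(rundir, stage, cfg, outputs):
        logger.info("%s: up to date, skipping", stage)
        return
    try:
        func(cfg, rundir)
    except Exception as e:
        raise RuntimeError(f"stage {stage!r} failed: {e}") from e
    inputs = [p for p in (cfg.counts_path, cfg.samples_path, cfg.pathways_path, cfg.taxonomy_path) if p]
    _record(rundir, stage, cfg, [Path(p) for p in inputs], outputs)


def run_all(cfg: PipelineConfig, force: bool = False) -> Path:
    """Run every stage in order; returns the run directory.

    A stage whose provenance matches the current parameters and whose
    outputs exist is skipped, making interrupted runs resumable.
    """
    skip_select = cfg.k is not None
    for stage in STAGES:
        if stage == "select_k" and skip_select:
            continue
        run_stage(cfg, stage, force=force)
    return Path(cfg.out_dir)
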