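"""Sample selection, ecosystem labeling, rare-KO filtering, CLR normalization.

The selection filters mirror standard practice for large metagenome
compilations: keep samples with no data-use restriction, a substantial
assembly (> 100,000 genes), adequate annotation (> 30% of genes with a KO),
estimated gene-copy data available, and a single read library (no combined
assemblies). Thresholds are strict inequalities.

KO abundances are compositional (each sample sums to an arbitrary sequencing
depth), so downstream statistics operate on the per-sample centered log-ratio
(CLR) transform in log base 2: a value of 0 means the KO's abundance equals
the geometric mean of its sample. Zeros are handled with a constant
pseudocount prior (default 0.5, the uniform prior commonly used for
point-estimate CLR of count data).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .profiles_io import CountMatrix, SampleTable

__all__ = [
    "QC_CRITERIA",
    "QCReport",
    "NormalizedMatrix",
    "apply_sample_qc",
    "assign_ecosystem_labels",
    "filter_rare_kos",
    "clr_normalize",
]

#: QC criteria, in reporting order. A sample passes overall iff all pass.
QC_CRITERIA = (
    "use_unrestricted",
    "enough_genes",
    "enough_annotated",
    "has_copy_data",
    "single_assembly",
)


@dataclass
class QCReport:
    """Per-sample pass/fail for each selection criterion."""

    table: pd.DataFrame  # index sample_id; bool column per criterion + "passed"

    @property
    def n_input(self) -> int:
        return len(self.table)

    @property
    def n_passed(self) -> int:
        return int(self.table["passed"].sum())

    def passed_samples(self) -> list[str]:
        return list(self.table.index[self.table["passed"]])

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index_label="sample_id")


def apply_sample_qc(
    samples: SampleTable,
    counts: CountMatrix,
    min_genes: int = 100_000,
    min_pct_annotated: float = 30.0,
) -> tuple[CountMatrix, QCReport]:
    """Filter count-matrix samples by the metadata selection criteria.

    Retains exactly the samples that are unrestricted, have strictly more
    than ``min_genes`` assembled genes and strictly more than
    ``min_pct_annotated`` percent KO-annotated genes, have gene-copy data,
    and are not combined assemblies. A missing metadata value fails its
    criterion (never defaulted to passing).
    """
    missing = [s for s in counts.sample_ids if s not in samples]
    if missing:
        raise KeyError(f"sample {missing[0]!r} absent from the sample table")
    idx = pd.Index(counts.sample_ids)

    def col(name: str) -> pd.Series:
        return samples.column(name).reindex(idx)

    checks = pd.DataFrame(index=idx)
    # strict ">" thresholds; boundary values are excluded
    checks["use_unrestricted"] = (col("use_restricted") == False).fillna(False)  # noqa: E712
    checks["enough_genes"] = (col("gene_count") > min_genes).fillna(False)
    checks["enough_annotated"] = (col("pct_ko_annotated") > min_pct_annotated).fillna(False)
    checks["has_copy_data"] = (col("has_copy_data") == True).fillna(False)  # noqa: E712
    checks["single_assembly"] = (col("is_combined_assembly") == False).fillna(False)  # noqa: E712
    checks = checks.astype(bool)
    checks["passed"] = checks[list(QC_CRITERIA)].all(axis=1)
    report = QCReport(checks)
    kept = report.passed_samples()
    if not kept:
        raise ValueError("no samples pass QC")
    return counts.subset_samples(kept), report


def assign_ecosystem_labels(samples: SampleTable, min_count: int = 100) -> SampleTable:
    """Derive an ``ecosystem_label`` column from the two ecosystem fields.

    A sample is labeled with its fine-grained ``ecosystem_type`` when strictly
    more than ``min_count`` samples share that type; otherwise the broader
    ``ecosystem`` field is used. Samples missing both fields are labeled
    ``"Unclassified"``. This collapses rare type labels into their broader
    category so no label describes only a handful of samples.
    """
    etype = samples.column("ecosystem_type")
    eco = samples.column("ecosystem")
    type_counts = etype.dropna().value_counts()
    common = set(type_counts.index[type_counts > min_count])

    def label(t: object, e: object) -> str:
        if pd.notna(t) and t in common:
            return str(t)
        if pd.notna(e):
            return str(e)
        if pd.notna(t):
            # rare type with no broader field: better a rare label than none
            return str(t)
        return "Unclassified"

    labels = pd.Series(
        [label(t, e) for t, e in zip(etype, eco)],
        index=samples.df.index,
        name="ecosystem_label",
    )
    return samples.with_column("ecosystem_label", labels)


def filter_rare_kos(counts: CountMatrix, min_prevalence: float = 0.10) -> CountMatrix:
    """Drop KOs present (count > 0) in less than ``min_prevalence`` of samples.

    A KO at exactly the threshold prevalence is retained (removal requires
    strictly "less than"). The sample set is unchanged.
    """
    if not 0 <= min_prevalence <= 1:
        raise ValueError("min_prevalence must be in [0, 1]")
    prevalence = (counts.values > 0).mean(axis=0)
    keep = prevalence >= min_prevalence
    if not keep.any():
        raise ValueError("prevalence filter removed every KO")
    kept_ids = [k for k, ok in zip(counts.ko_ids, keep) if ok]
    return counts.subset_kos(kept_ids)


@dataclass
class NormalizedMatrix:
    """Per-sample CLR-transformed abundances on the log2 scale.

    Each row has mean 0 over the retained KOs: positive values are above the
    sample's geometric mean abundance, negative below.
    """

    sample_ids: list[str]
    ko_ids: list[str]
    values: np.ndarray
    prior: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.isfinite(self.values).all():
            raise ValueError("normalized matrix contains non-finite values")
        rowmeans = self.values.mean(axis=1)
        if np.abs(rowmeans).max() > 1e-9:
            raise ValueError("per-sample CLR mean deviates from 0 beyond 1e-9")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_kos(self) -> int:
        return len(self.ko_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.ko_ids)

    def ko_index(self, ko_id: str) -> int:
        try:
            return self.ko_ids.index(ko_id)
        except ValueError:
            raise KeyError(f"unknown KO id {ko_id!r}") from None


def clr_normalize(counts: CountMatrix, prior: float = 0.5) -> NormalizedMatrix:
    """Centered log2-ratio transform per sample with a pseudocount prior.

    ``clr[i, j] = log2(x[i, j] + prior) - mean_k log2(x[i, k] + prior)``,
    the mean running over the KOs retained in ``counts``. With ``prior = 0``
    (allowed only for strictly positive matrices) the transform is invariant
    to per-sample rescaling of the counts.
    """
    if prior < 0:
        raise ValueError("prior must be >= 0")
    if prior == 0 and (counts.values <= 0).any():
        raise ValueError("prior = 0 requires strictly positive counts")
    logx = np.log2(counts.values + prior)
    clr = logx - logx.mean(axis=1, keepdims=True)
    # re-center to kill accumulated floating-point drift in the row means
    clr -= clr.mean(axis=1, keepdims=True)
    return NormalizedMatrix(
        list(counts.sample_ids), list(counts.ko_ids), clr, prior=prior
    )
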