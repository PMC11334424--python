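"""Relating clusters to GC content and taxonomy; per-KO GC regression.

Assembled-metagenome GC content is a community-aggregate genomic trait taken
from sample metadata (a fraction in [0, 1], never recomputed from sequence).
Cluster-level differences in GC or in per-domain taxonomic proportions are
tested exactly like marker KOs: Kruskal-Wallis across clusters followed by
Dunn's pairwise post-hoc tests.

The per-KO association with GC content is an ordinary least-squares fit of
CLR abundance on GC, summarized by the Pearson correlation r and tested with
the Wald t statistic t = r * sqrt((n-2)/(1-r^2)) on n-2 degrees of freedom
(identical to the slope's t test in simple regression). Computation is
vectorized across KOs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import t as t_dist

from .marker_analysis import dunn_posthoc, kruskal_wallis
from .profiles_io import TAXONOMY_DOMAINS, TaxonomyTable

logger = logging.getLogger(__name__)

__all__ = [
    "GroupComparison",
    "compare_across_clusters",
    "taxonomy_proportions",
    "gc_ko_regression",
    "rank_gc_correlates",
]


@dataclass
class GroupComparison:
    """KW + Dunn comparison of one per-sample variable across clusters."""

    variable: str
    groups: dict  # cluster -> np.ndarray of non-missing values
    h: float
    p: float
    dunn: dict  # (i, j) -> (z, p_bonferroni)
    n_missing: int = 0

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "variable": self.variable,
                "cluster_a": i,
                "cluster_b": j,
                "H": self.h,
                "kw_p": self.p,
                "dunn_z": z,
                "dunn_p": p,
            }
            for (i, j), (z, p) in sorted(self.dunn.items())
        ]
        return pd.DataFrame(rows)


def compare_across_clusters(values, labels, variable: str = "value") -> GroupComparison:
    """Kruskal-Wallis and Dunn tests of a per-sample variable across clusters.

    Missing values are dropped per sample (count logged); every cluster must
    keep at least 2 non-missing values.
    """
    vals = np.asarray(pd.Series(values, dtype=float))
    labels = np.asarray(labels, dtype=int)
    if len(vals) != len(labels):
        raise ValueError("values and labels differ in length")
    ok = np.isfinite(vals)
    n_missing = int((~ok).sum())
    if n_missing:
        logger.info("%s: dropped %d samples with missing values", variable, n_missing)
    clusters = np.unique(labels)
    groups: dict[int, np.ndarray] = {}
    for c in clusters:
        g = vals[(labels == c) & ok]
        if len(g) == 0:
            raise ValueError(f"cluster {c} has no non-missing {variable} values")
        if len(g) < 2:
            raise ValueError(f"cluster {c} has fewer than 2 {variable} values")
        groups[int(c)] = g
    ordered = [groups[int(c)] for c in clusters]
    h, p = kruskal_wallis(ordered)
    dunn_idx = dunn_posthoc(ordered)
    dunn = {
        (int(clusters[i]), int(clusters[j])): zp for (i, j), zp in dunn_idx.items()
    }
    return GroupComparison(variable, groups, h, p, dunn, n_missing)


def taxonomy_proportions(tax: TaxonomyTable) -> pd.DataFrame:
    """Per-sample domain fractions of contig counts (rows sum to 1).

    Samples with zero total contigs are dropped with a warning.
    """
    counts = tax.df
    totals = counts.sum(axis=1)
    zero = totals == 0
    if zero.any():
        logger.warning(
            "taxonomy_proportions: dropped %d samples with zero contigs", int(zero.sum())
        )
    kept = counts[~zero]
    fractions = kept.div(totals[~zero], axis=0)
    return fractions[list(TAXONOMY_DOMAINS)]


def gc_ko_regression(X, gc, bonferroni: bool = True) -> pd.DataFrame:
    """OLS of each KO's CLR abundance on GC content.

    Returns one row per KO: slope (CLR units per GC fraction), intercept,
    pearson_r, wald_p (two-sided, t with n-2 df), optional Bonferroni
    adjustment across KOs, and n. Samples with missing GC are dropped.
    A KO with constant abundance gets r = 0, p = 1.
    """
    arr = np.asarray(X.values, dtype=float) if hasattr(X, "values") else np.asarray(X, dtype=float)
    ko_ids = list(X.ko_ids) if hasattr(X, "ko_ids") else [str(j) for j in range(arr.shape[1])]
    gc = np.asarray(pd.Series(gc, dtype=float))
    if len(gc) != arr.shape[0]:
        raise ValueError("gc length does not match sample count")
    ok = np.isfinite(gc)
    gc, arr = gc[ok], arr[ok]
    n = len(gc)
    if n < 3:
        raise ValueError("need at least 3 samples with GC content")
    x = gc - gc.mean()
    sxx = float((x**2).sum())
    if sxx == 0:
        raise ValueError("GC content is constant; regression undefined")
    y = arr - arr.mean(axis=0, keepdims=True)
    sxy = x @ y                       # per KO
    syy = (y**2).sum(axis=0)
    slope = sxy / sxx
    intercept = arr.mean(axis=0) - slope * gc.mean()
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(syy > 0, sxy / np.sqrt(sxx * syy), 0.0)
    r = np.clip(r, -1.0, 1.0)
    one_minus_r2 = np.maximum(1.0 - r**2, 0.0)
    with np.errstate(divide="ignore"):
        t_stat = r * np.sqrt((n - 2) / np.where(one_minus_r2 > 0, one_minus_r2, np.inf))
    p = 2.0 * t_dist.sf(np.abs(t_stat), df=n - 2)
    p = np.where(one_minus_r2 == 0, 0.0, p)     # perfect fit
    p = np.where(syy == 0, 1.0, p)              # constant KO abundance
    out = pd.DataFrame(
        {
            "slope": slope,
            "intercept": intercept,
            "pearson_r": r,
            "wald_p": p,
            "n": n,
        },
        index=pd.Index(ko_ids, name="ko_id"),
    )
    if bonferroni:
        out["wald_p_bonferroni"] = np.minimum(out["wald_p"] * len(out), 1.0)
    return out


def rank_gc_correlates(results: pd.DataFrame, n_top: int = 20) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Top positively and negatively GC-correlated KOs by Pearson r.

    Ties broken by KO id for deterministic output.
    """
    pos = results.sort_values(
        by=["pearson_r", "ko_id"], ascending=[False, True], kind="mergesort"
    ).head(n_top)
    neg = results.sort_values(
        by=["pearson_r", "ko_id"], ascending=[True, True], kind="mergesort"
    ).head(n_top)
    return pos, neg
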