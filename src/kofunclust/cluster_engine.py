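"""Unsupervised clustering of CLR profiles with bootstrap model selection.

Two partitioning methods are offered on Euclidean distance in CLR space:
k-means (Lloyd's algorithm with k-means++ seeding and multiple restarts,
implemented here so every iteration can be checked for monotone
within-cluster sum of squares) and Ward agglomerative clustering (scipy
linkage cut at k).

Model selection follows a bootstrap protocol: the data are repeatedly
subsampled without replacement and re-clustered; each replicate is scored by
its mean silhouette (cohesion) and by the adjusted Rand index against a
reference model fitted on the full data (stability). The (method, k) with
the best mean silhouette wins, ties broken by mean ARI, then smaller k.

To limit overfitting, the final k-means model is trained on a random half of
the samples and every sample (training and held out) is then assigned to its
nearest centroid. Each main cluster can be split further into sub-clusters
by re-running k-means within it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import cdist
from sklearn.metrics import adjusted_rand_score, silhouette_score

__all__ = [
    "ClusterModel",
    "BootstrapReport",
    "kmeans_fit",
    "ward_fit",
    "silhouette_mean",
    "adjusted_rand",
    "bootstrap_select",
    "fit_final",
    "subcluster",
    "pca_project",
]


def _as_matrix(X) -> tuple[np.ndarray, list[str] | None]:
    """Accept a NormalizedMatrix, DataFrame, or plain array."""
    if hasattr(X, "values") and hasattr(X, "sample_ids"):
        return np.asarray(X.values, dtype=float), list(X.sample_ids)
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), list(X.index.astype(str))
    arr = np.asarray(X, dtype=float)
    if arr.ndim != 2:
        raise ValueError("expected a 2-D sample x feature matrix")
    return arr, None


@dataclass
class ClusterModel:
    """A fitted partition of samples.

    ``labels`` holds an integer in ``[0, k)`` for every sample (for k-means,
    held-out samples are assigned to the nearest centroid). ``centroids`` is
    k x n_features for k-means, None for Ward. ``training_sample_ids``
    records the subset the model was fitted on when it differs from all
    samples.
    """

    method: str
    k: int
    labels: np.ndarray
    sample_ids: list[str] | None = None
    centroids: np.ndarray | None = None
    training_sample_ids: list[str] | None = None
    seed: int | None = None
    inertia: float | None = None
    linkage_matrix: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        counts = np.bincount(self.labels, minlength=self.k)
        if (self.labels < 0).any() or (self.labels >= self.k).any():
            raise ValueError("labels must lie in [0, k)")
        if (counts == 0).any():
            raise ValueError(f"cluster {int(np.argmin(counts))} is empty")

    def predict(self, X) -> np.ndarray:
        if self.centroids is None:
            raise ValueError("nearest-centroid assignment requires a k-means model")
        arr, _ = _as_matrix(X)
        return np.argmin(cdist(arr, self.centroids, "sqeuclidean"), axis=1)

    def members(self, cluster: int) -> np.ndarray:
        return np.flatnonzero(self.labels == cluster)

    def to_frame(self) -> pd.DataFrame:
        idx = self.sample_ids if self.sample_ids is not None else range(len(self.labels))
        return pd.DataFrame({"cluster": self.labels}, index=pd.Index(idx, name="sample_id"))


# ---------------------------------------------------------------- k-means


def _kmeans_pp_init(X: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """k-means++ seeding: new centers drawn with probability ~ D^2."""
    n = X.shape[0]
    centers = np.empty((k, X.shape[1]))
    centers[0] = X[rng.integers(n)]
    d2 = cdist(X, centers[:1], "sqeuclidean").ravel()
    for c in range(1, k):
        total = d2.sum()
        if total <= 0:  # all points coincide with chosen centers
            centers[c] = X[rng.integers(n)]
            continue
        idx = rng.choice(n, p=d2 / total)
        centers[c] = X[idx]
        d2 = np.minimum(d2, cdist(X, centers[c : c + 1], "sqeuclidean").ravel())
    return centers


def _lloyd(
    X: np.ndarray,
    centers: np.ndarray,
    max_iter: int,
    tol: float,
) -> tuple[np.ndarray, np.ndarray, float]:
    k = centers.shape[0]
    prev_wcss = math.inf
    labels = np.zeros(X.shape[0], dtype=int)
    for _ in range(max_iter):
        d2 = cdist(X, centers, "sqeuclidean")
        labels = np.argmin(d2, axis=1)
        # an empty cluster is re-seeded at the point farthest from its center
        repaired = False
        min_d2 = np.min(d2, axis=1)
        for c in range(k):
            if not (labels == c).any():
                far = int(np.argmax(min_d2))
                labels[far] = c
                min_d2[far] = -1.0  # never steal the same point twice
                repaired = True
        if repaired:
            prev_wcss = math.inf  # repair may raise the objective; restart baseline
        wcss = 0.0
        new_centers = centers.copy()
        for c in range(k):
            pts = X[labels == c]
            new_centers[c] = pts.mean(axis=0)
            wcss += float(((pts - new_centers[c]) ** 2).sum())
        # Lloyd monotonicity: the objective never increases between iterations
        assert wcss <= prev_wcss + 1e-8 * max(1.0, abs(prev_wcss)), (
            "k-means objective increased"
        )
        shift = float(((new_centers - centers) ** 2).sum())
        centers = new_centers
        if shift <= tol or wcss == prev_wcss:
            prev_wcss = wcss
            break
        prev_wcss = wcss
    return labels, centers, prev_wcss


def kmeans_fit(
    X,
    k: int,
    seed: int,
    n_init: int = 10,
    max_iter: int = 300,
    tol: float = 1e-6,
) -> ClusterModel:
    """Lloyd's k-means with k-means++ init; best of ``n_init`` restarts.

    Deterministic given ``seed``. Raises if ``k`` exceeds the sample count.
    """
    arr, ids = _as_matrix(X)
    n = arr.shape[0]
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > n:
        raise ValueError(f"k = {k} exceeds the {n} available samples")
    rng = np.random.default_rng(seed)
    best: tuple[float, np.ndarray, np.ndarray] | None = None
    for _ in range(n_init):
        centers0 = _kmeans_pp_init(arr, k, rng)
        labels, centers, wcss = _lloyd(arr, centers0, max_iter, tol)
        if best is None or wcss < best[0]:
            best = (wcss, labels, centers)
    wcss, labels, centers = best
    return ClusterModel(
        method="kmeans",
        k=k,
        labels=labels,
        sample_ids=ids,
        centroids=centers,
        training_sample_ids=ids,
        seed=seed,
        inertia=wcss,
    )


# ------------------------------------------------------------------ Ward


def ward_fit(X, k: int) -> ClusterModel:
    """Ward agglomerative clustering (Lance-Williams update) cut at k."""
    arr, ids = _as_matrix(X)
    n = arr.shape[0]
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > n:
        raise ValueError(f"k = {k} exceeds the {n} available samples")
    if n == 1:
        return ClusterModel("ward", 1, np.zeros(1, dtype=int), sample_ids=ids)
    Z = linkage(arr, method="ward")
    raw = fcluster(Z, t=k, criterion="maxclust")
    # relabel to contiguous 0..k'-1 in order of first appearance
    _, labels = np.unique(raw, return_inverse=True)
    return ClusterModel(
        method="ward",
        k=int(labels.max()) + 1,
        labels=labels,
        sample_ids=ids,
        training_sample_ids=ids,
        linkage_matrix=Z,
    )


# ------------------------------------------------------------ partition scores


def silhouette_mean(X, labels) -> float:
    """Mean silhouette coefficient (Euclidean); singletons score 0."""
    arr, _ = _as_matrix(X)
    labels = np.asarray(labels, dtype=int)
    if len(labels) != arr.shape[0]:
        raise ValueError("labels length does not match sample count")
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise ValueError("silhouette requires at least 2 clusters")
    if len(uniq) == arr.shape[0]:
        return 0.0  # every point is a singleton
    return float(silhouette_score(arr, labels, metric="euclidean"))


def adjusted_rand(labels_a, labels_b) -> float:
    """Chance-corrected agreement between two partitions of the same items."""
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.shape != b.shape:
        raise ValueError("partitions must label the same samples")
    return float(adjusted_rand_score(a, b))


# --------------------------------------------------------- model selection


_FIT_SEED_SPACE = 2**31


def _derive_seed(seed: int, *parts) -> int:
    """Stable per-task seed from a master seed and a context tuple."""
    h = np.uint64(seed & 0xFFFFFFFF)
    for p in parts:
        token = str(p).encode()
        for byte in token:
            h = np.uint64((int(h) * 1000003 + byte) % (2**63))
    return int(h) % _FIT_SEED_SPACE


def _fit(method: str, X: np.ndarray, k: int, seed: int, n_init: int) -> ClusterModel:
    if method == "kmeans":
        return kmeans_fit(X, k, seed=seed, n_init=n_init)
    if method == "ward":
        return ward_fit(X, k)
    raise ValueError(f"unknown clustering method {method!r}")


@dataclass
class BootstrapReport:
    """Silhouette and stability-ARI vectors per (method, k) replicate."""

    silhouette: dict  # (method, k) -> np.ndarray of length B
    ari: dict  # (method, k) -> np.ndarray of length B
    B: int
    subsample_fraction: float
    chosen_k: int
    chosen_method: str
    seed: int

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (method, k), sil in sorted(self.silhouette.items()):
            ari = self.ari[(method, k)]
            rows.append(
                {
                    "method": method,
                    "k": k,
                    "mean_silhouette": float(np.mean(sil)),
                    "sd_silhouette": float(np.std(sil)),
                    "mean_ari": float(np.mean(ari)),
                    "sd_ari": float(np.std(ari)),
                    "B": self.B,
                }
            )
        return pd.DataFrame(rows)


def bootstrap_select(
    X,
    k_range: Iterable[int],
    methods: Sequence[str] = ("kmeans", "ward"),
    B: int = 100,
    subsample_fraction: float = 0.8,
    seed: int = 0,
    n_init: int = 10,
) -> BootstrapReport:
    """Choose (method, k) by repeated subsampling.

    For each of ``B`` replicates a without-replacement subsample of
    ``subsample_fraction`` of the samples is clustered for every candidate
    (method, k); the replicate records its mean silhouette and its ARI
    against a full-data reference model restricted to the subsample. The
    winner maximizes mean silhouette, ties broken by higher mean ARI, then
    smaller k.
    """
    if B < 2:
        raise ValueError("B must be >= 2")
    if not 0 < subsample_fraction <= 1:
        raise ValueError("subsample_fraction must be in (0, 1]")
    arr, _ = _as_matrix(X)
    n = arr.shape[0]
    m = int(math.floor(subsample_fraction * n))
    ks = sorted(set(int(k) for k in k_range))
    if not ks:
        raise ValueError("empty k range")
    if min(ks) < 2:
        raise ValueError("k must be >= 2 for model selection")
    if max(ks) > m:
        raise ValueError(f"k = {max(ks)} exceeds subsample size {m}")

    rng = np.random.default_rng(seed)
    subsamples = [rng.choice(n, size=m, replace=False) for _ in range(B)]

    reference = {
        (method, k): _fit(method, arr, k, _derive_seed(seed, "ref", method, k), n_init)
        for method in methods
        for k in ks
    }
    sil: dict = {key: np.empty(B) for key in reference}
    ari: dict = {key: np.empty(B) for key in reference}
    for b, idx in enumerate(subsamples):
        sub = arr[idx]
        for method in methods:
            for k in ks:
                model = _fit(method, sub, k, _derive_seed(seed, "boot", method, k, b), n_init)
                key = (method, k)
                sil[key][b] = silhouette_mean(sub, model.labels)
                ari[key][b] = adjusted_rand(model.labels, reference[key].labels[idx])

    def sort_key(key):
        method, k = key
        return (-np.mean(sil[key]), -np.mean(ari[key]), k, methods.index(method))

    best_method, best_k = min(sil.keys(), key=sort_key)
    return BootstrapReport(
        silhouette=sil,
        ari=ari,
        B=B,
        subsample_fraction=subsample_fraction,
        chosen_k=best_k,
        chosen_method=best_method,
        seed=seed,
    )


def fit_final(
    X,
    k: int,
    seed: int,
    method: str = "kmeans",
    holdout_fraction: float = 0.5,
    n_init: int = 10,
) -> ClusterModel:
    """Fit the production model on a random ``holdout_fraction`` of samples.

    Training on half the data guards against overfitting the partition to
    every sample; held-out samples are then assigned to the nearest centroid
    so every sample receives a label. ``holdout_fraction`` is the fraction
    *used for training*; 1.0 reduces to a plain full-data fit.
    """
    if method != "kmeans":
        raise ValueError("the final model uses k-means (nearest-centroid predict)")
    if not 0 < holdout_fraction <= 1:
        raise ValueError("holdout_fraction must be in (0, 1]")
    arr, ids = _as_matrix(X)
    n = arr.shape[0]
    n_train = max(k, int(math.floor(holdout_fraction * n)))
    rng = np.random.default_rng(seed)
    train_idx = np.sort(rng.choice(n, size=n_train, replace=False))
    trained = kmeans_fit(arr[train_idx], k, seed=_derive_seed(seed, "final"), n_init=n_init)
    labels = np.argmin(cdist(arr, trained.centroids, "sqeuclidean"), axis=1)
    train_ids = [ids[i] for i in train_idx] if ids is not None else None
    return ClusterModel(
        method="kmeans",
        k=k,
        labels=labels,
        sample_ids=ids,
        centroids=trained.centroids,
        training_sample_ids=train_ids,
        seed=seed,
        inertia=trained.inertia,
    )


def subcluster(
    X,
    model: ClusterModel,
    k_sub: int = 2,
    seed: int = 0,
    n_init: int = 10,
) -> Mapping[int, ClusterModel]:
    """Split each cluster of ``model`` into ``k_sub`` k-means sub-clusters."""
    if k_sub < 1:
        raise ValueError("k_sub must be >= 1")
    arr, ids = _as_matrix(X)
    if len(model.labels) != arr.shape[0]:
        raise ValueError("model labels do not match the matrix")
    out: dict[int, ClusterModel] = {}
    for c in range(model.k):
        members = model.members(c)
        if k_sub > 1 and len(members) < 2 * k_sub:
            raise ValueError(
                f"cluster {c} has only {len(members)} samples; "
                f"need >= {2 * k_sub} for {k_sub} sub-clusters"
            )
        sub_ids = [ids[i] for i in members] if ids is not None else None
        sub = kmeans_fit(arr[members], min(k_sub, len(members)),
                         seed=_derive_seed(seed, "sub", c), n_init=n_init)
        sub.sample_ids = sub_ids
        sub.training_sample_ids = sub_ids
        out[c] = sub
    return out


def pca_project(X, n_components: int = 5) -> np.ndarray:
    """Centered PCA scores for the top components (by explained variance).

    Signs follow the usual convention that the largest-magnitude loading of
    each component is positive, making the scores deterministic.
    """
    arr, _ = _as_matrix(X)
    n, p = arr.shape
    if n_components < 1 or n_components > min(n, p):
        raise ValueError(
            f"n_components must be in [1, {min(n, p)}], got {n_components}"
        )
    centered = arr - arr.mean(axis=0, keepdims=True)
    U, S, Vt = np.linalg.svd(centered, full_matrices=False)
    # deterministic sign: flip so each component's largest |loading| is positive
    signs = np.sign(Vt[np.arange(Vt.shape[0]), np.argmax(np.abs(Vt), axis=1)])
    signs[signs == 0] = 1.0
    scores = U * S
    return scores[:, :n_components] * signs[:n_components]
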