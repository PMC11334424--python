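"""Independent brute-force oracles used to validate the statistics.

Deliberately naive implementations (double loops, exhaustive search,
first-principles formulas) kept separate from the package code paths they
check.
"""

from __future__ import annotations

from itertools import combinations
from math import comb, sqrt

import numpy as np
from scipy.stats import norm, rankdata


def silhouette_brute(X: np.ndarray, labels: np.ndarray) -> float:
    """Mean silhouette via the textbook double loop."""
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    n = len(labels)
    dist = np.array(
        [[sqrt(((X[i] - X[j]) ** 2).sum()) for j in range(n)] for i in range(n)]
    )
    scores = []
    for i in range(n):
        same = [j for j in range(n) if labels[j] == labels[i] and j != i]
        if not same:
            scores.append(0.0)
            continue
        a = np.mean([dist[i][j] for j in same])
        b = min(
            np.mean([dist[i][j] for j in range(n) if labels[j] == c])
            for c in set(labels)
            if c != labels[i]
        )
        scores.append((b - a) / max(a, b))
    return float(np.mean(scores))


def adjusted_rand_brute(a, b) -> float:
    """ARI from first-principles pair counting over the contingency table."""
    a = list(a)
    b = list(b)
    n = len(a)
    sum_ij = 0
    for ca in set(a):
        for cb in set(b):
            nij = sum(1 for x, y in zip(a, b) if x == ca and y == cb)
            sum_ij += comb(nij, 2)
    sum_a = sum(comb(a.count(c), 2) for c in set(a))
    sum_b = sum(comb(b.count(c), 2) for c in set(b))
    expected = sum_a * sum_b / comb(n, 2)
    max_index = 0.5 * (sum_a + sum_b)
    if max_index == expected:
        return 1.0
    return (sum_ij - expected) / (max_index - expected)


def ward_merges_brute(X: np.ndarray) -> list[frozenset]:
    """Greedy Ward agglomeration by minimum ESS increase; returns the
    partition (as frozensets of point indices) after every merge."""
    X = np.asarray(X, dtype=float)
    clusters: list[list[int]] = [[i] for i in range(len(X))]
    snapshots = []
    while len(clusters) > 1:
        best = None
        for i, j in combinations(range(len(clusters)), 2):
            a, b = clusters[i], clusters[j]
            ma, mb = X[a].mean(axis=0), X[b].mean(axis=0)
            delta = len(a) * len(b) / (len(a) + len(b)) * ((ma - mb) ** 2).sum()
            if best is None or delta < best[0]:
                best = (delta, i, j)
        _, i, j = best
        merged = clusters[i] + clusters[j]
        clusters = [c for idx, c in enumerate(clusters) if idx not in (i, j)]
        clusters.append(merged)
        snapshots.append([frozenset(c) for c in clusters])
    return snapshots


def dunn_brute(groups) -> dict:
    """Scalar Dunn post-hoc from the joint mid-rank formula, pair by pair."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    pooled = np.concatenate(groups)
    N = len(pooled)
    ranks = rankdata(pooled)
    tie = 0.0
    for v in set(pooled.tolist()):
        t = int((pooled == v).sum())
        tie += t**3 - t
    var = N * (N + 1) / 12 - tie / (12 * (N - 1))
    offsets = np.cumsum([0] + [len(g) for g in groups])
    mean_rank = [
        ranks[offsets[i] : offsets[i + 1]].mean() for i in range(len(groups))
    ]
    npairs = len(groups) * (len(groups) - 1) // 2
    out = {}
    for i, j in combinations(range(len(groups)), 2):
        if var <= 0:
            out[(i, j)] = (0.0, 1.0)
            continue
        z = (mean_rank[i] - mean_rank[j]) / sqrt(
            var * (1 / len(groups[i]) + 1 / len(groups[j]))
        )
        out[(i, j)] = (z, min(1.0, 2 * float(norm.sf(abs(z))) * npairs))
    return out
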