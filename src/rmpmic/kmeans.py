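"""Exact one-dimensional k-means (the Euclidean baseline).

For scalar data the optimal sum-of-squared-error k-partition is contiguous
in sorted order, so the global optimum can be found by dynamic programming
over split points — no random initialisation, fully deterministic.  This is
the baseline the mini-cluster method is compared against.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.utils.validation import check_is_fitted


def _segment_sse(prefix: np.ndarray, prefix2: np.ndarray, i: int, j: int) -> float:
    """SSE of sorted[i:j] around its mean, from prefix sums."""
    n = j - i
    s = prefix[j] - prefix[i]
    s2 = prefix2[j] - prefix2[i]
    return s2 - s * s / n


def kmeans_1d(values: Sequence[float], k: int = 2) -> list[int]:
    """Globally optimal 1-D k-means partition.

    Returns a cluster label per input value, with clusters numbered by
    first occurrence in the input (cluster 0 contains the first value).
    Optimal clusters of scalar data are intervals of the sorted values, so
    all C(n-1, k-1) contiguous splits are explored by DP and the minimum
    total within-cluster sum of squares wins; ties resolve to the
    lexicographically smallest split-point set.

    Raises
    ------
    ValueError
        If ``k`` exceeds the number of distinct values (some cluster would
        be forced empty or duplicated).
    """
    v = np.asarray(values, dtype=float)
    n = v.size
    if n == 0:
        raise ValueError("cannot cluster an empty value list")
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    if k > np.unique(v).size:
        raise ValueError(f"k={k} exceeds the number of distinct values "
                         f"({np.unique(v).size})")

    order = np.argsort(v, kind="stable")
    sv = v[order]
    prefix = np.concatenate([[0.0], np.cumsum(sv)])
    prefix2 = np.concatenate([[0.0], np.cumsum(sv * sv)])

    # dp[m][j] = min SSE of splitting sorted[0:j] into m segments
    INF = float("inf")
    dp = [[INF] * (n + 1) for _ in range(k + 1)]
    back = [[0] * (n + 1) for _ in range(k + 1)]
    dp[0][0] = 0.0
    for m in range(1, k + 1):
        for j in range(m, n + 1):
            for i in range(m - 1, j):
                if dp[m - 1][i] == INF:
                    continue
                cost = dp[m - 1][i] + _segment_sse(prefix, prefix2, i, j)
                if cost < dp[m][j] - 1e-15:
                    dp[m][j] = cost
                    back[m][j] = i

    # recover segment boundaries over the sorted order
    bounds = [n]
    j = n
    for m in range(k, 0, -1):
        j = back[m][j]
        bounds.append(j)
    bounds.reverse()  # [0, b1, ..., n]

    sorted_labels = np.empty(n, dtype=int)
    for seg, (lo, hi) in enumerate(zip(bounds[:-1], bounds[1:])):
        sorted_labels[order[lo:hi]] = seg

    # renumber by first occurrence in the input
    remap: dict[int, int] = {}
    out = []
    for lab in sorted_labels:
        if lab not in remap:
            remap[lab] = len(remap)
        out.append(remap[lab])
    return out


def partition_sse(values: Sequence[float], labels: Sequence[int]) -> float:
    """Total within-cluster sum of squares of an arbitrary partition."""
    v = np.asarray(values, dtype=float)
    lab = np.asarray(labels)
    return float(sum(((v[lab == c] - v[lab == c].mean()) ** 2).sum()
                     for c in np.unique(lab)))


class KMeans1D(BaseEstimator, ClusterMixin):
    """Deterministic, globally optimal k-means for scalar features.

    Parameters
    ----------
    n_clusters : int, default 2

    Attributes
    ----------
    labels_ : ndarray of shape (n,)
        Cluster per sample, numbered by first occurrence.
    cluster_centers_ : ndarray of shape (n_clusters, 1)
        Cluster means.
    inertia_ : float
        Total within-cluster sum of squares (the global minimum).
    """

    def __init__(self, n_clusters: int = 2):
        self.n_clusters = n_clusters

    def fit(self, X, y=None) -> "KMeans1D":
        v = np.asarray(X, dtype=float).reshape(-1)
        labels = np.asarray(kmeans_1d(v, self.n_clusters))
        self.labels_ = labels
        self.cluster_centers_ = np.array(
            [[v[labels == c].mean()] for c in range(self.n_clusters)])
        self.inertia_ = partition_sse(v, labels)
        return self

    def fit_predict(self, X, y=None) -> np.ndarray:
        return self.fit(X).labels_

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "cluster_centers_")
        v = np.asarray(X, dtype=float).reshape(-1, 1)
        return np.argmin((v - self.cluster_centers_.T) ** 2, axis=1)
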