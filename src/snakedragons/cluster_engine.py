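"""Partitioning of objects by consensus, k-means, and Ward clustering.

The centerpiece is resampling-based consensus clustering (Monti-style):
many random subsets of the objects are each partitioned by k-means, and
the *consensus matrix* records, for every pair of objects, the fraction
of co-sampled runs in which they landed in the same cluster — an
empirical probability that the pair belongs together.  Final labels cut
a hierarchical tree built on ``1 - consensus``; the number of clusters
is chosen by the Calinski-Harabasz criterion over a scanned range of k.

Reproducibility protocol (relied upon by replay tests): resample ``r``
uses the generator ``default_rng([seed, r])``, draws the subset indices
first, then one k-means seed per scanned k, in ascending k order.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform
from sklearn.cluster import KMeans

from .matrix_distance import PairwiseDistanceMatrix


class ClusterError(Exception):
    pass


@dataclass
class ConsensusMatrix:
    object_ids: list[str]
    co_cluster_counts: np.ndarray  # N x N int
    co_sample_counts: np.ndarray  # N x N int
    values: np.ndarray  # co_cluster / co_sample, imputed where undefined

    @property
    def n_imputed_pairs(self) -> int:
        iu = np.triu_indices(len(self.object_ids), 1)
        return int(np.sum(self.co_sample_counts[iu] == 0))


@dataclass
class ClusteringResult:
    labels_by_k: dict[int, np.ndarray]
    calinski_by_k: dict[int, float]
    chosen_k: int
    method_tag: str
    seed: int | None = None
    resample_count: int | None = None
    subset_fraction: float | None = None

    @property
    def labels(self) -> np.ndarray:
        return self.labels_by_k[self.chosen_k]


def _seed_int(rng_seed) -> int:
    if isinstance(rng_seed, np.random.Generator):
        return int(rng_seed.integers(2**31))
    return int(rng_seed)


def kmeans_partition(
    X: np.ndarray, k: int, n_restarts: int = 10, rng_seed: int | np.random.Generator = 0
) -> np.ndarray:
    """k-means labels (1..k) from the best of ``n_restarts`` k-means++ runs."""
    X = np.asarray(X, dtype=float)
    if k > X.shape[0]:
        raise ClusterError(f"k={k} exceeds the number of objects ({X.shape[0]})")
    if not np.all(np.isfinite(X)):
        raise ClusterError("non-finite vector entries")
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=_seed_int(rng_seed))
    return km.fit_predict(X) + 1


def hierarchical_partition(
    vectors: np.ndarray | None = None,
    distances: PairwiseDistanceMatrix | np.ndarray | None = None,
    k: int = 2,
    method: str = "ward",
) -> tuple[np.ndarray, np.ndarray]:
    """Agglomerative clustering cut into k groups.

    Either Euclidean Ward on raw ``vectors`` or a declared linkage on a
    precomputed distance matrix.  Returns (labels 1..k, merge list) —
    the merge list is the standard 4-column linkage matrix (children,
    height, size).  Given identical input the merge sequence is
    deterministic (ties resolved by scipy's fixed scan order).
    """
    if (vectors is None) == (distances is None):
        raise ClusterError("provide exactly one of vectors / distances")
    if vectors is not None:
        X = np.asarray(vectors, dtype=float)
        n = X.shape[0]
        condensed = pdist(X)
    else:
        D = distances.values if isinstance(distances, PairwiseDistanceMatrix) else np.asarray(distances, dtype=float)
        n = D.shape[0]
        condensed = squareform(np.asarray(D, dtype=float), checks=False)
    if not np.all(np.isfinite(condensed)):
        raise ClusterError("non-finite distances")
    if k > n:
        raise ClusterError(f"k={k} exceeds the number of objects ({n})")
    Z = linkage(condensed, method=method)
    labels = fcluster(Z, t=k, criterion="maxclust")
    if len(np.unique(labels)) != k:
        # maxclust can undershoot when heights tie; force k by cutting merges
        heights = np.sort(Z[:, 2])
        for t in np.unique(heights)[::-1]:
            labels = fcluster(Z, t=t - 1e-12, criterion="distance")
            if len(np.unique(labels)) >= k:
                break
        labels = _merge_down(labels, condensed, n, k)
    return labels.astype(int), Z


def _merge_down(labels: np.ndarray, condensed: np.ndarray, n: int, k: int) -> np.ndarray:
    """Reduce an over-split labelling to exactly k clusters by merging
    the closest pair of clusters (average linkage on the condensed
    distances) repeatedly."""
    D = squareform(condensed)
    labels = labels.copy()
    while len(np.unique(labels)) > k:
        uniq = np.unique(labels)
        best, pair = np.inf, None
        for a_i in range(len(uniq)):
            for b_i in range(a_i + 1, len(uniq)):
                ma, mb = labels == uniq[a_i], labels == uniq[b_i]
                d = D[np.ix_(ma, mb)].mean()
                if d < best:
                    best, pair = d, (uniq[a_i], uniq[b_i])
        labels[labels == pair[1]] = pair[0]
    # relabel 1..k in first-appearance order
    remap = {old: new for new, old in enumerate(dict.fromkeys(labels), start=1)}
    return np.array([remap[l] for l in labels])


def calinski(X: np.ndarray, labels: np.ndarray) -> float:
    """Calinski-Harabasz criterion CH = [B/(k-1)] / [W/(N-k)].

    B is the between-cluster dispersion (size-weighted squared centroid
    distances from the grand mean), W the pooled within-cluster sum of
    squares.  W = 0 (duplicated points per cluster) returns +inf.
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    N = X.shape[0]
    uniq = np.unique(labels)
    k = len(uniq)
    if k < 2 or k >= N:
        raise ClusterError(f"Calinski undefined for k={k} with N={N}")
    grand = X.mean(axis=0)
    B = W = 0.0
    for c in uniq:
        pts = X[labels == c]
        cen = pts.mean(axis=0)
        B += len(pts) * float(np.sum((cen - grand) ** 2))
        W += float(np.sum((pts - cen) ** 2))
    if W == 0.0:
        return float("inf")
    return (B / (k - 1)) / (W / (N - k))


def consensus_cluster(
    X: np.ndarray,
    k_range=range(2, 9),
    n_resamples: int = 1000,
    subset_fraction: float = 0.8,
    rng_seed: int = 0,
    n_restarts: int = 10,
    with_replacement: bool = False,
    linkage_method: str = "ward",
    object_ids: list[str] | None = None,
) -> tuple[dict[int, ConsensusMatrix], ClusteringResult]:
    """Resampling-based consensus clustering over a scanned k range.

    Each resample selects ``ceil(subset_fraction * N)`` objects —
    distinct by default (Monti subsampling); ``with_replacement=True``
    draws with replacement and collapses duplicates for counting — and
    partitions them with k-means for every scanned k.  Consensus values
    are co-cluster counts over co-sample counts; pairs never co-sampled
    (vanishingly rare at the defaults) are imputed with the global mean
    consensus under a warning.  Final labels per k cut a hierarchical
    tree on ``1 - consensus``; Calinski is evaluated on ``X`` itself
    (the geometry the clustering saw) and ``chosen_k`` maximizes it,
    smallest k winning ties.
    """
    X = np.asarray(X, dtype=float)
    N = X.shape[0]
    k_range = sorted(k_range)
    if N < 4:
        raise ClusterError("consensus clustering needs N >= 4")
    s = math.ceil(subset_fraction * N)
    if s < max(k_range):
        raise ClusterError(
            f"subset size {s} is smaller than max k {max(k_range)}"
        )
    ids = object_ids or [str(i) for i in range(N)]

    co_sample = np.zeros((N, N), dtype=np.int64)
    co_cluster = {k: np.zeros((N, N), dtype=np.int64) for k in k_range}
    for r in range(n_resamples):
        rng = np.random.default_rng([int(rng_seed), r])
        idx = rng.choice(N, size=s, replace=with_replacement)
        uniq_idx = np.unique(idx)
        co_sample[np.ix_(uniq_idx, uniq_idx)] += 1
        for k in k_range:
            km_seed = int(rng.integers(2**31))
            labels = kmeans_partition(X[idx], k, n_restarts, km_seed)
            for c in range(1, k + 1):
                members = np.unique(idx[labels == c])
                co_cluster[k][np.ix_(members, members)] += 1

    consensus_by_k: dict[int, ConsensusMatrix] = {}
    labels_by_k: dict[int, np.ndarray] = {}
    ch_by_k: dict[int, float] = {}
    iu = np.triu_indices(N, 1)
    for k in k_range:
        with np.errstate(invalid="ignore", divide="ignore"):
            values = np.where(co_sample > 0, co_cluster[k] / np.maximum(co_sample, 1), np.nan)
        undefined = np.isnan(values[iu])
        if undefined.any():
            fill = float(np.nanmean(values[iu])) if not np.all(undefined) else 0.0
            warnings.warn(
                f"{int(undefined.sum())} object pair(s) never co-sampled; "
                f"imputing global mean consensus {fill:.3f}"
            )
            vals = values.copy()
            vals[np.isnan(vals)] = fill
            values = vals
        np.fill_diagonal(values, 1.0)
        consensus_by_k[k] = ConsensusMatrix(list(ids), co_cluster[k], co_sample, values)
        labels, _ = hierarchical_partition(
            distances=1.0 - values, k=k, method=linkage_method
        )
        labels_by_k[k] = labels
        ch_by_k[k] = calinski(X, labels) if k < N else float("nan")
    chosen_k = max(k_range, key=lambda k: (ch_by_k[k], -k))
    result = ClusteringResult(
        labels_by_k,
        ch_by_k,
        chosen_k,
        method_tag="consensus",
        seed=int(rng_seed),
        resample_count=n_resamples,
        subset_fraction=subset_fraction,
    )
    return consensus_by_k, result


def scan_k(
    X: np.ndarray,
    k_range=range(2, 9),
    method: str = "ward",
    rng_seed: int = 0,
    n_restarts: int = 10,
) -> ClusteringResult:
    """Plain k-means or Ward labels for every scanned k, with Calinski
    model selection (the non-consensus counterpart of
    :func:`consensus_cluster`)."""
    X = np.asarray(X, dtype=float)
    labels_by_k, ch_by_k = {}, {}
    for k in sorted(k_range):
        if method == "kmeans":
            labels = kmeans_partition(X, k, n_restarts, np.random.default_rng([int(rng_seed), k]))
        elif method == "ward":
            labels, _ = hierarchical_partition(vectors=X, k=k)
        else:
            raise ClusterError(f"unknown method {method!r}")
        labels_by_k[k] = labels
        ch_by_k[k] = calinski(X, labels) if 2 <= k < X.shape[0] else float("nan")
    chosen_k = max(sorted(k_range), key=lambda k: (ch_by_k[k], -k))
    return ClusteringResult(labels_by_k, ch_by_k, chosen_k, method_tag=method, seed=int(rng_seed))
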