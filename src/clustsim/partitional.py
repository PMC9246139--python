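"""Partitioning-around-medoids and complete-linkage hierarchical clustering.

Both methods operate on the Euclidean distance matrix of the raw indicator
values (which the generator produces at unit variance, so no rescaling is
applied).  The number of clusters is chosen by maximizing the average
silhouette width over k = 2..5; the one-cluster possibility, which the
silhouette cannot express, is screened first with the Duda-Hart test on the
method's own two-cluster partition: if the test does not reject homogeneity
at level alpha, a single cluster is reported.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform
from scipy.stats import norm
from sklearn.metrics import silhouette_score

from .results import ClusterResult

__all__ = [
    "DudaHartResult",
    "euclidean_distance_matrix",
    "pam_cluster",
    "hac_complete",
    "cut_tree",
    "avg_silhouette",
    "duda_hart",
    "select_k_partitional",
]


def euclidean_distance_matrix(x: np.ndarray) -> np.ndarray:
    """Square symmetric matrix of pairwise Euclidean (L2) distances."""
    return squareform(pdist(np.asarray(x, dtype=float)))


# ---------------------------------------------------------------------------
# PAM


def pam_cluster(
    dist: np.ndarray, k: int, max_swap: int = 100
) -> tuple[np.ndarray, np.ndarray]:
    """Partitioning around medoids: greedy BUILD then steepest-descent SWAP.

    BUILD seeds the first medoid at the point minimizing total distance to
    all others, then adds the medoid giving the largest cost reduction.
    SWAP repeatedly applies the single (medoid, non-medoid) exchange that
    most reduces the total distance of units to their nearest medoid, until
    no exchange improves the cost (a local optimum) or ``max_swap`` passes.

    Returns ``(labels, medoids)`` with labels in 1..k indexed by medoid
    position.
    """
    dist = np.asarray(dist, dtype=float)
    n = dist.shape[0]
    if not 1 <= k <= n:
        raise ValueError(f"need 1 <= k <= n, got k={k}, n={n}")

    # BUILD
    medoids = [int(np.argmin(dist.sum(axis=1)))]
    d_near = dist[:, medoids[0]].copy()
    while len(medoids) < k:
        reduction = np.maximum(d_near[:, None] - dist, 0.0).sum(axis=0)
        reduction[medoids] = -np.inf
        j = int(np.argmax(reduction))
        medoids.append(j)
        d_near = np.minimum(d_near, dist[:, j])

    medoids_arr = np.array(medoids)
    # SWAP
    for _ in range(max_swap):
        dmed = dist[:, medoids_arr]                    # (n, k)
        near_pos = np.argmin(dmed, axis=1)
        d1 = dmed[np.arange(n), near_pos]
        if k > 1:
            dmed_masked = dmed.copy()
            dmed_masked[np.arange(n), near_pos] = np.inf
            d2 = dmed_masked.min(axis=1)
        else:
            d2 = np.full(n, np.inf)
        current_cost = d1.sum()

        is_medoid = np.zeros(n, dtype=bool)
        is_medoid[medoids_arr] = True
        candidates = np.flatnonzero(~is_medoid)
        if candidates.size == 0:  # k == n: nothing to swap
            break
        best = (0.0, None, None)
        for pos in range(k):
            # nearest-medoid distance once medoid `pos` is removed
            alt = np.where(near_pos == pos, d2, d1)
            costs = np.minimum(alt[:, None], dist[:, candidates]).sum(axis=0)
            i = int(np.argmin(costs))
            gain = current_cost - costs[i]
            if gain > best[0] + 1e-12:
                best = (gain, pos, candidates[i])
        if best[1] is None:
            break
        medoids_arr[best[1]] = best[2]

    labels = np.argmin(dist[:, medoids_arr], axis=1) + 1
    labels[medoids_arr] = np.arange(1, k + 1)  # medoids belong to themselves
    return labels, medoids_arr


def pam_cost(dist: np.ndarray, medoids: np.ndarray) -> float:
    """Total distance of every unit to its nearest medoid."""
    return float(np.asarray(dist)[:, np.asarray(medoids)].min(axis=1).sum())


# ---------------------------------------------------------------------------
# HAC


def hac_complete(dist: np.ndarray) -> np.ndarray:
    """Complete-linkage agglomeration; returns the SciPy linkage matrix.

    Merge heights equal the maximum pairwise distance between the merged
    clusters and are non-decreasing down the tree.
    """
    dist = np.asarray(dist, dtype=float)
    if dist.ndim == 2:
        dist = squareform(dist, checks=False)
    return linkage(dist, method="complete")


def cut_tree(tree: np.ndarray, k: int) -> np.ndarray:
    """Cut a linkage tree into exactly k groups (labels 1..k)."""
    n = tree.shape[0] + 1
    if not 1 <= k <= n:
        raise ValueError(f"need 1 <= k <= n, got k={k}, n={n}")
    return fcluster(tree, t=k, criterion="maxclust")


# ---------------------------------------------------------------------------
# selection criteria


def avg_silhouette(dist: np.ndarray, labels: np.ndarray) -> float:
    """Average silhouette width ``mean_i (b_i - a_i) / max(a_i, b_i)``.

    ``a_i`` is the mean distance of unit i to its own cluster, ``b_i`` the
    smallest mean distance to another cluster; singleton clusters score 0
    (the standard convention).  Requires at least two non-empty clusters.
    """
    labels = np.asarray(labels)
    if np.unique(labels).size < 2:
        raise ValueError("average silhouette needs at least 2 clusters")
    return float(silhouette_score(np.asarray(dist), labels, metric="precomputed"))


@dataclass(frozen=True)
class DudaHartResult:
    """Duda-Hart test of one cluster against a given two-cluster split.

    ``je1`` is the within-group sum of squares of the whole sample about its
    mean, ``je2`` the pooled within-cluster sum of squares of the
    2-partition.  Homogeneity is rejected when ``je2/je1`` falls below the
    normal-approximation critical value at level alpha.
    """

    je1: float
    je2: float
    ratio: float
    critical_value: float
    alpha: float
    reject_homogeneity: bool


def duda_hart_critical_value(n: int, p: int, alpha: float = 0.05) -> float:
    """One-sided normal-approximation threshold for Je(2)/Je(1)."""
    z = norm.ppf(1.0 - alpha)
    return 1.0 - 2.0 / (np.pi * p) - z * np.sqrt(
        2.0 * (1.0 - 8.0 / (np.pi**2 * p)) / (n * p)
    )


def duda_hart(x: np.ndarray, labels2: np.ndarray, alpha: float = 0.05) -> DudaHartResult:
    """Test the one-cluster hypothesis against a 2-cluster partition."""
    x = np.asarray(x, dtype=float)
    labels2 = np.asarray(labels2)
    groups = np.unique(labels2)
    if groups.size != 2:
        raise ValueError(f"labels2 must have exactly 2 non-empty groups, got {groups.size}")
    n, p = x.shape
    je1 = float(((x - x.mean(axis=0)) ** 2).sum())
    je2 = 0.0
    for grp in groups:
        xg = x[labels2 == grp]
        je2 += float(((xg - xg.mean(axis=0)) ** 2).sum())
    ratio = je2 / je1 if je1 > 0 else 0.0
    crit = duda_hart_critical_value(n, p, alpha)
    return DudaHartResult(
        je1=je1,
        je2=je2,
        ratio=ratio,
        critical_value=float(crit),
        alpha=alpha,
        reject_homogeneity=bool(ratio < crit),
    )


# ---------------------------------------------------------------------------
# cluster-number selection


def select_k_partitional(
    x: np.ndarray,
    method: str = "pam",
    k_range: tuple[int, ...] = (2, 3, 4, 5),
    alpha: float = 0.05,
) -> ClusterResult:
    """Choose k for PAM or complete-linkage HAC.

    The method's own 2-cluster partition feeds the Duda-Hart screen: if
    homogeneity is not rejected at ``alpha`` the result is a single cluster.
    Otherwise the average silhouette width is computed at every k in
    ``k_range`` and the maximizer wins, ties broken toward smaller k.
    """
    x = np.asarray(x, dtype=float)
    if method not in ("pam", "hac"):
        raise ValueError(f"method must be 'pam' or 'hac', got {method!r}")
    k_range = tuple(sorted(k_range))
    if x.shape[0] <= max(k_range):
        raise ValueError("need more units than the largest candidate k")

    dist = euclidean_distance_matrix(x)
    tree = hac_complete(dist) if method == "hac" else None

    def labels_at(k: int) -> np.ndarray:
        if method == "pam":
            labels, _ = pam_cluster(dist, k)
            return labels
        return cut_tree(tree, k)

    labels_by_k = {k: labels_at(k) for k in k_range}
    labels2 = labels_by_k.get(2, labels_at(2))
    dh = duda_hart(x, labels2, alpha=alpha)

    sil = pd.Series(
        {k: avg_silhouette(dist, labels_by_k[k]) for k in k_range},
        name="avg_silhouette",
    )
    sil.index.name = "k"

    if not dh.reject_homogeneity:
        return ClusterResult(
            method=method,
            k_selected=1,
            labels=np.ones(x.shape[0], dtype=int),
            criterion_by_k=sil,
            duda_hart=dh,
        )

    # ties toward smaller k: idxmax returns the first maximum and the index
    # is sorted ascending
    k_best = int(sil.idxmax())
    return ClusterResult(
        method=method,
        k_selected=k_best,
        labels=labels_by_k[k_best],
        criterion_by_k=sil,
        duda_hart=dh,
    )
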