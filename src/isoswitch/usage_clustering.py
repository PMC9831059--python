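"""Change of total isoform usage and clustering of usage-change profiles.

The per-gene usage-change profile is the vector, over consecutive time-point
pairs, of the L1 distance between the gene's isoform-fraction vectors
(replicates averaged before differencing).  Each entry lies in [0, 2]; the
upper bound 2 is attained by a complete two-isoform flip.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from sklearn.cluster import DBSCAN, OPTICS, AgglomerativeClustering, KMeans

from isoswitch.core_data import TimeCourseMatrix, relative_abundance

__all__ = [
    "UsageChangeProfile",
    "ClusterResult",
    "total_usage_change",
    "profiles_to_frame",
    "cluster_profiles",
    "ward_merge_heights",
    "dtw_distance",
]


@dataclass
class UsageChangeProfile:
    gene_id: str
    values: np.ndarray  # length T-1, entries in [0, 2]


@dataclass
class ClusterResult:
    assignments: dict[str, int]
    prototypes: dict[int, np.ndarray]  # per-dimension median of member profiles
    method: str
    params: dict


def total_usage_change(
    m: TimeCourseMatrix, genes: Sequence[str] | None = None
) -> list[UsageChangeProfile]:
    """Per-gene L1 change of replicate-averaged isoform fractions.

    Single-isoform genes yield all-zero profiles (their fraction is constant
    1 wherever the gene is expressed).
    """
    I = relative_abundance(m)
    T, R = I.n_timepoints, m.n_replicates
    wanted = set(genes) if genes is not None else None
    out = []
    for gene_id, rows in I.gene_groups().items():
        if wanted is not None and gene_id not in wanted:
            continue
        frac = I.values[rows].reshape(len(rows), T, R).mean(axis=2)  # (k, T)
        delta = np.abs(np.diff(frac, axis=1)).sum(axis=0)  # (T-1,)
        out.append(UsageChangeProfile(gene_id, delta))
    return out


def profiles_to_frame(profiles: list[UsageChangeProfile]) -> pd.DataFrame:
    data = {p.gene_id: p.values for p in profiles}
    df = pd.DataFrame.from_dict(data, orient="index")
    df.index.name = "gene_id"
    df.columns = [f"delta_{i}" for i in range(df.shape[1])]
    return df


# ---------------------------------------------------------------------------
# Distances
# ---------------------------------------------------------------------------

def dtw_distance(x: np.ndarray, y: np.ndarray) -> float:
    """Classic dynamic-time-warping distance with unit step and |.| cost."""
    n, m = len(x), len(y)
    D = np.full((n + 1, m + 1), np.inf)
    D[0, 0] = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            cost = abs(x[i - 1] - y[j - 1])
            D[i, j] = cost + min(D[i - 1, j], D[i, j - 1], D[i - 1, j - 1])
    return float(D[n, m])


def _pairwise_distances(X: np.ndarray, metric: str) -> np.ndarray:
    n = X.shape[0]
    if metric == "euclidean":
        from scipy.spatial.distance import cdist

        return cdist(X, X)
    if metric == "pearson":
        sd = X.std(axis=1)
        if np.any(sd == 0):
            # constant profiles correlate with nothing; fall back to 1 off-diagonal
            D = np.ones((n, n)) - np.eye(n)
            ok = sd > 0
            if ok.sum() >= 2:
                sub = 1.0 - np.corrcoef(X[ok])
                D[np.ix_(ok, ok)] = np.clip(sub, 0, None)
            return D
        return np.clip(1.0 - np.corrcoef(X), 0, None)
    if metric == "dtw":
        D = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                D[i, j] = D[j, i] = dtw_distance(X[i], X[j])
        return D
    raise ValueError("metric must be euclidean, pearson or dtw")


def _kmedoids(D: np.ndarray, k: int, rng: np.random.Generator, n_iter: int = 100) -> np.ndarray:
    """Simple PAM-style alternation on a precomputed distance matrix."""
    n = D.shape[0]
    medoids = rng.choice(n, size=k, replace=False)
    for _ in range(n_iter):
        labels = np.argmin(D[:, medoids], axis=1)
        new = medoids.copy()
        for c in range(k):
            members = np.flatnonzero(labels == c)
            if len(members) == 0:
                continue
            within = D[np.ix_(members, members)].sum(axis=1)
            new[c] = members[np.argmin(within)]
        if np.array_equal(np.sort(new), np.sort(medoids)):
            break
        medoids = new
    return np.argmin(D[:, medoids], axis=1)


def cluster_profiles(
    profiles: list[UsageChangeProfile],
    method: str = "agglomerative-ward",
    k: int | None = None,
    metric: str = "euclidean",
    seed: int = 0,
    **params,
) -> ClusterResult:
    """Cluster usage-change profiles; prototypes are per-dimension medians.

    Methods: ``agglomerative-ward`` (euclidean only), ``kmeans`` (euclidean
    only), ``kmedoids``, ``dbscan``, ``optics`` (any metric, computed on a
    precomputed distance matrix).  Partitional methods require ``k``.
    """
    if not profiles:
        raise ValueError("no profiles to cluster")
    genes = [p.gene_id for p in profiles]
    X = np.vstack([p.values for p in profiles])
    rng = np.random.default_rng(seed)

    needs_k = method in ("agglomerative-ward", "kmeans", "kmedoids")
    if needs_k:
        if k is None:
            raise ValueError(f"method {method} requires k")
        if k > len(profiles):
            raise ValueError("k exceeds number of profiles")

    if method == "agglomerative-ward":
        if metric != "euclidean":
            raise ValueError("ward linkage requires the euclidean metric")
        labels = AgglomerativeClustering(n_clusters=k, linkage="ward").fit_predict(X)
    elif method == "kmeans":
        if metric != "euclidean":
            raise ValueError("kmeans requires the euclidean metric")
        labels = KMeans(n_clusters=k, random_state=seed, n_init=10).fit_predict(X)
    elif method == "kmedoids":
        labels = _kmedoids(_pairwise_distances(X, metric), k, rng)
    elif method == "dbscan":
        D = _pairwise_distances(X, metric)
        labels = DBSCAN(metric="precomputed", **params).fit_predict(D)
    elif method == "optics":
        D = _pairwise_distances(X, metric)
        opts = {"min_samples": params.pop("min_samples", 5), **params}
        labels = OPTICS(metric="precomputed", **opts).fit_predict(D)
    else:
        raise ValueError(f"unknown clustering method: {method}")

    assignments = {g: int(c) for g, c in zip(genes, labels)}
    prototypes = {
        int(c): np.median(X[labels == c], axis=0)
        for c in sorted(set(int(c) for c in labels))
        if c != -1  # DBSCAN/OPTICS noise label carries no prototype
    }
    return ClusterResult(
        assignments=assignments,
        prototypes=prototypes,
        method=method,
        params={"k": k, "metric": metric, "seed": seed, **params},
    )


def ward_merge_heights(profiles: list[UsageChangeProfile]) -> pd.DataFrame:
    """Ward-linkage merge heights, largest first, to support manual choice of k.

    Row ``n_clusters=c`` gives the height at which the partition into ``c``
    clusters merges into ``c-1``.
    """
    X = np.vstack([p.values for p in profiles])
    Z = linkage(X, method="ward")
    heights = Z[:, 2][::-1]
    return pd.DataFrame(
        {"n_clusters": np.arange(2, len(heights) + 2), "merge_height": heights}
    )
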