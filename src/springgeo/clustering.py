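"""Clustering of hyperbolic radial coordinates and the spectral baseline.

Radial coordinates (ball norms of a hyperbolic embedding) are clustered with
1-D k-means; the number of clusters comes from the elbow of the WSS curve and
stability is assessed by repeated runs.  The driver cluster is the one whose
intra-cluster rescaled-stiffness distribution is closest (minimum two-sample
Kolmogorov-Smirnov statistic) to the global off-diagonal distribution.  A
spectral-clustering baseline with the eigengap heuristic is included.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import ks_2samp
from sklearn.cluster import KMeans

from .embedding import EmbeddingResult
from .network_io import GeneNetwork
from .spring_model import StiffnessMatrix

logger = logging.getLogger(__name__)


@dataclass
class RadialClustering:
    """1-D k-means result with optional stability distributions.

    Labels are 1-based and relabeled so centroids are ascending.
    """

    k: int
    labels: np.ndarray
    centroids: np.ndarray
    wss: float
    bss: float
    runs: int = 1
    wss_distribution: np.ndarray | None = None
    bss_distribution: np.ndarray | None = None

    @property
    def total_ss(self) -> float:
        return self.wss + self.bss


@dataclass
class DriverReport:
    """Per-cluster intra-pair statistics and the flagged driver cluster."""

    table: pd.DataFrame
    driver_cluster: int | None
    global_values: np.ndarray
    intra_values: dict[int, np.ndarray] = field(default_factory=dict)


@dataclass
class SpectralBaseline:
    k: int
    labels: np.ndarray
    cluster_sizes: np.ndarray
    wss_per_cluster: np.ndarray
    wss: float
    bss: float


def total_pairs(n: int) -> int:
    """Number of unordered node pairs, n(n-1)/2."""
    return n * (n - 1) // 2


def radial_coordinates(emb: EmbeddingResult) -> np.ndarray:
    """Ball norms of a hyperbolic embedding; errors for other models."""
    if emb.model.name != "hyperbolic":
        raise ValueError(
            f"radial coordinates are defined for hyperbolic embeddings, "
            f"got {emb.model.name!r}"
        )
    return np.linalg.norm(emb.coordinates, axis=1)


def _fit_kmeans_1d(
    values: np.ndarray, k: int, restarts: int, seed: int | None
) -> tuple[np.ndarray, np.ndarray, float]:
    x = values.reshape(-1, 1)
    km = KMeans(
        n_clusters=k, n_init=restarts, max_iter=300, random_state=seed
    ).fit(x)
    centroids = km.cluster_centers_.ravel()
    order = np.argsort(centroids)
    relabel = np.empty(k, dtype=int)
    relabel[order] = np.arange(1, k + 1)
    labels = relabel[km.labels_]
    centroids = centroids[order]
    wss = float(km.inertia_)
    return labels, centroids, wss


def kmeans_radial(
    values: np.ndarray,
    k: int,
    restarts: int = 25,
    seed: int | None = None,
) -> RadialClustering:
    """1-D k-means (k-means++ init, Lloyd iterations, best of ``restarts``)."""
    values = np.asarray(values, dtype=float).ravel()
    if k < 1:
        raise ValueError("k must be >= 1")
    if len(values) < k:
        raise ValueError("need at least k values")
    if len(np.unique(values)) < k:
        raise ValueError("k exceeds the number of distinct values")
    mean = values.mean()
    total = float(np.sum((values - mean) ** 2))
    if k == 1:
        return RadialClustering(
            k=1,
            labels=np.ones(len(values), dtype=int),
            centroids=np.array([mean]),
            wss=total,
            bss=0.0,
        )
    labels, centroids, wss = _fit_kmeans_1d(values, k, restarts, seed)
    return RadialClustering(
        k=k, labels=labels, centroids=centroids, wss=wss, bss=total - wss
    )


def elbow_k(values: np.ndarray, k_max: int = 25, restarts: int = 10,
            seed: int | None = None) -> int:
    """Elbow of the WSS curve over k = 1..k_max.

    Returns the k maximizing the perpendicular distance of (k, WSS(k)) from
    the chord joining (1, WSS(1)) and (k_max, WSS(k_max)).
    """
    values = np.asarray(values, dtype=float).ravel()
    if k_max < 2:
        raise ValueError("k_max must be >= 2")
    if len(values) <= k_max:
        raise ValueError("need more values than k_max")
    if len(np.unique(values)) == 1:
        warnings.warn("constant values: elbow undefined, returning k=1",
                      RuntimeWarning, stacklevel=2)
        return 1
    k_max = min(k_max, len(np.unique(values)))
    ks = np.arange(1, k_max + 1)
    wss = np.array(
        [kmeans_radial(values, int(k), restarts=restarts, seed=seed).wss
         for k in ks],
        dtype=float,
    )
    # a perfect clustering (WSS ~ 0) before k_max is the elbow by definition
    zero = np.flatnonzero(wss <= 1e-12 * max(wss[0], 1e-300))
    if len(zero) and ks[zero[0]] > 1:
        return int(ks[zero[0]])
    # perpendicular distance from the chord (k1, w1)-(kmax, wmax)
    x1, y1 = float(ks[0]), wss[0]
    x2, y2 = float(ks[-1]), wss[-1]
    chord = np.hypot(x2 - x1, y2 - y1)
    dist = np.abs((y2 - y1) * ks - (x2 - x1) * wss + x2 * y1 - y2 * x1) / chord
    return int(ks[np.argmax(dist)])


def stability_analysis(
    values: np.ndarray,
    k: int,
    runs: int = 1000,
    seed: int | None = None,
    restarts: int = 1,
) -> RadialClustering:
    """Repeat k-means ``runs`` times with independent per-run seeds.

    Returns the last fit with the per-run WSS/BSS distributions attached.
    """
    if runs < 2:
        raise ValueError("runs must be >= 2")
    child_seeds = np.random.SeedSequence(seed).generate_state(runs)
    wss_runs = np.empty(runs)
    bss_runs = np.empty(runs)
    result: RadialClustering | None = None
    for i in range(runs):
        result = kmeans_radial(
            values, k, restarts=restarts, seed=int(child_seeds[i] % (2**31))
        )
        wss_runs[i] = result.wss
        bss_runs[i] = result.bss
    assert result is not None
    result.runs = runs
    result.wss_distribution = wss_runs
    result.bss_distribution = bss_runs
    logger.info(
        "stability: median BSS/WSS = %.3g over %d runs",
        float(np.median(bss_runs / np.where(wss_runs > 0, wss_runs, np.inf))),
        runs,
    )
    return result


def intra_cluster_pairs(labels: np.ndarray) -> pd.DataFrame:
    """Per-cluster intra-pair counts over ALL node pairs (dense matrix view).

    For a cluster of size n_c the intra-pair count is n_c (n_c - 1) / 2 and
    the fraction is taken over all n (n - 1) / 2 node pairs.
    """
    labels = np.asarray(labels)
    n = len(labels)
    total = total_pairs(n)
    clusters, sizes = np.unique(labels, return_counts=True)
    counts = sizes * (sizes - 1) // 2
    return pd.DataFrame(
        {
            "cluster": clusters,
            "size": sizes,
            "intra_pairs": counts,
            "fraction": counts / total,
        }
    )


def intra_cluster_edge_fractions(
    g: GeneNetwork, labels: np.ndarray
) -> pd.DataFrame:
    """Secondary table: intra-cluster counts restricted to graph edges."""
    labels = np.asarray(labels)
    clusters = np.unique(labels)
    counts = {int(c): 0 for c in clusters}
    for i, j in g.edges:
        if labels[i] == labels[j]:
            counts[int(labels[i])] += 1
    m = g.n_edges
    return pd.DataFrame(
        {
            "cluster": list(counts),
            "intra_edges": list(counts.values()),
            "fraction": [c / m for c in counts.values()],
        }
    )


def driver_cluster(
    k: StiffnessMatrix | np.ndarray,
    labels: np.ndarray,
    min_pairs: int = 30,
) -> DriverReport:
    """Flag the cluster whose intra-pair stiffness distribution best matches
    the global off-diagonal distribution (minimum two-sample KS statistic).

    Clusters with fewer than ``min_pairs`` intra pairs are not eligible.
    """
    if isinstance(k, StiffnessMatrix):
        if k.rescaled is None:
            raise ValueError("stiffness matrix is not rescaled")
        mat = k.rescaled
    else:
        mat = np.asarray(k, dtype=float)
    labels = np.asarray(labels)
    n = mat.shape[0]
    if len(labels) != n:
        raise ValueError("label count must match matrix size")
    iu = np.triu_indices(n, k=1)
    global_values = mat[iu]

    records = []
    intra_values: dict[int, np.ndarray] = {}
    for c in np.unique(labels):
        members = np.flatnonzero(labels == c)
        n_c = len(members)
        n_pairs = n_c * (n_c - 1) // 2
        if n_pairs > 0:
            sub = mat[np.ix_(members, members)]
            vals = sub[np.triu_indices(n_c, k=1)]
        else:
            vals = np.empty(0)
        intra_values[int(c)] = vals
        ks_stat = (
            float(ks_2samp(vals, global_values).statistic)
            if n_pairs >= min_pairs
            else np.nan
        )
        records.append(
            {
                "cluster": int(c),
                "size": n_c,
                "intra_pairs": n_pairs,
                "fraction": n_pairs / total_pairs(n),
                "ks": ks_stat,
            }
        )
    table = pd.DataFrame(records)
    eligible = table.dropna(subset=["ks"])
    if eligible.empty:
        warnings.warn(
            f"no cluster reaches min_pairs={min_pairs}; no driver flagged",
            RuntimeWarning,
            stacklevel=2,
        )
        driver = None
    else:
        driver = int(eligible.loc[eligible["ks"].idxmin(), "cluster"])
    return DriverReport(
        table=table,
        driver_cluster=driver,
        global_values=global_values,
        intra_values=intra_values,
    )


# ---------------------------------------------------------------------------
# spectral baseline


def _normalized_laplacian(w: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Symmetric normalized Laplacian; zero-degree nodes removed with warning.

    Returns (L, kept_indices).
    """
    w = np.asarray(w, dtype=float)
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise ValueError("affinity matrix must be square")
    if not np.allclose(w, w.T, atol=1e-10):
        raise ValueError("affinity matrix must be symmetric")
    if np.any(w < 0):
        raise ValueError("affinity matrix must be non-negative")
    deg = w.sum(axis=1)
    kept = np.flatnonzero(deg > 0)
    if len(kept) < w.shape[0]:
        warnings.warn(
            f"removed {w.shape[0] - len(kept)} zero-degree node(s) before "
            "the normalized Laplacian",
            RuntimeWarning,
            stacklevel=3,
        )
        w = w[np.ix_(kept, kept)]
        deg = deg[kept]
    d_inv_sqrt = 1.0 / np.sqrt(deg)
    lap = np.eye(len(deg)) - d_inv_sqrt[:, None] * w * d_inv_sqrt[None, :]
    return 0.5 * (lap + lap.T), kept


def eigengap_k(w: np.ndarray, k_max: int = 10) -> int:
    """Number of clusters maximizing the eigengap of the normalized Laplacian.

    Eigenvalues are sorted ascending; returns the k <= k_max maximizing
    ``lambda_{k+1} - lambda_k``.
    """
    lap, _ = _normalized_laplacian(w)
    eigvals = np.linalg.eigvalsh(lap)
    k_max = min(k_max, len(eigvals) - 1)
    gaps = eigvals[1 : k_max + 1] - eigvals[:k_max]
    return int(np.argmax(gaps) + 1)


def spectral_clustering(
    w: np.ndarray,
    k: int,
    seed: int | None = None,
    restarts: int = 25,
) -> SpectralBaseline:
    """Normalized spectral clustering with WSS/BSS in spectral-coordinate space.

    Rows of the first-k eigenvector matrix are normalized to unit length and
    clustered with k-means.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    lap, kept = _normalized_laplacian(w)
    n = lap.shape[0]
    if k > n:
        raise ValueError("k exceeds the number of nodes")
    eigvals, eigvecs = np.linalg.eigh(lap)
    u = eigvecs[:, :k]
    norms = np.linalg.norm(u, axis=1)
    nz = norms > 0
    u[nz] = u[nz] / norms[nz, None]
    km = KMeans(n_clusters=k, n_init=restarts, max_iter=300,
                random_state=seed).fit(u)
    labels = km.labels_ + 1
    wss_per_cluster = np.array(
        [
            float(np.sum((u[labels == c] - km.cluster_centers_[c - 1]) ** 2))
            for c in range(1, k + 1)
        ]
    )
    mean = u.mean(axis=0)
    total = float(np.sum((u - mean) ** 2))
    wss = float(wss_per_cluster.sum())
    sizes = np.array([int(np.sum(labels == c)) for c in range(1, k + 1)])
    return SpectralBaseline(
        k=k,
        labels=labels,
        cluster_sizes=sizes,
        wss_per_cluster=wss_per_cluster,
        wss=wss,
        bss=total - wss,
    )
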