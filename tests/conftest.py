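"""Shared fixtures and independent oracles used across the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from springgeo.synthetic import fixture_graphs


@pytest.fixture(scope="session")
def fixtures():
    return fixture_graphs()


def dp_kmeans_1d_wss(values: np.ndarray, k: int) -> float:
    """Exact optimal 1-D k-means WSS by dynamic programming.

    Optimal 1-D clusters are contiguous in sorted order; O(k n^2) DP over
    segment boundaries with prefix-sum segment costs.
    """
    x = np.sort(np.asarray(values, dtype=float))
    n = len(x)
    pref = np.concatenate(([0.0], np.cumsum(x)))
    pref2 = np.concatenate(([0.0], np.cumsum(x**2)))

    def seg_cost(i: int, j: int) -> float:  # x[i..j-1]
        cnt = j - i
        s = pref[j] - pref[i]
        s2 = pref2[j] - pref2[i]
        return s2 - s * s / cnt

    inf = float("inf")
    dp = np.full((k + 1, n + 1), inf)
    dp[0, 0] = 0.0
    for kk in range(1, k + 1):
        for j in range(kk, n + 1):
            best = inf
            for i in range(kk - 1, j):
                if dp[kk - 1, i] < inf:
                    cand = dp[kk - 1, i] + seg_cost(i, j)
                    if cand < best:
                        best = cand
            dp[kk, j] = best
    return float(dp[k, n])


def make_driver_instance(
    seed: int, n_per: int = 20, n_clusters: int = 3, target: int = 3
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Planted driver-cluster simulation.

    Returns (radial_values, labels, stiffness_matrix).  Radial values form
    ``n_clusters`` separated bands.  Intra-pair stiffness of the ``target``
    cluster and all cross pairs are drawn from a two-component mixture; the
    other clusters' intra pairs come from the first component only, so the
    target cluster's intra distribution matches the global one best.
    """
    rng = np.random.default_rng(seed)
    n = n_per * n_clusters
    labels = np.repeat(np.arange(1, n_clusters + 1), n_per)
    centers = np.linspace(0.2, 0.8, n_clusters)
    radial = centers[labels - 1] + rng.normal(0.0, 0.01, size=n)

    def comp1(size):
        return np.clip(rng.normal(0.2, 0.03, size), 0.0, 1.0)

    def mixture(size):
        which = rng.random(size) < 0.5
        vals = comp1(size)
        vals[which] = np.clip(rng.normal(0.8, 0.03, int(which.sum())), 0.0, 1.0)
        return vals

    k = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            same = labels[i] == labels[j]
            if same and labels[i] == target:
                v = mixture(1)[0]
            elif same:
                v = comp1(1)[0]
            else:
                v = mixture(1)[0]
            k[i, j] = k[j, i] = v
    return radial, labels, k
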