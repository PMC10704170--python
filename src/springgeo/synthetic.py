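"""Planted-geometry point sets, exact distance matrices, threshold graphs,
and tiny hand-checkable fixture graphs for testing every pipeline stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .embedding import MetricModel, pairwise_model_distances
from .network_io import GeneNetwork, network_from_edges
from .spring_model import DissimilarityMatrix


@dataclass
class PlantedConfiguration:
    """Points sampled in one model space together with exact distances."""

    model: MetricModel
    coords: np.ndarray
    true_distances: np.ndarray
    seed: int
    params: dict = field(default_factory=dict)


def sample_points(
    model: MetricModel | str,
    n: int,
    dim: int,
    scale: float = 1.0,
    seed: int = 0,
) -> PlantedConfiguration:
    """Sample ``n`` points in a model space, deterministically given ``seed``.

    ``scale`` is the box side for the Euclidean model, the sphere radius for
    the spherical model, and the native disk radius R for the (2-D only)
    hyperbolic model, where the radial density is proportional to sinh(r)
    (quasi-uniform in hyperbolic area) and points are returned in
    Poincare-ball coordinates.
    """
    if isinstance(model, str):
        model = MetricModel(model, curvature=scale if model == "spherical" else 1.0)
    if n < 3:
        raise ValueError("n must be >= 3")
    if dim < 2:
        raise ValueError("dim must be >= 2")
    rng = np.random.default_rng(seed)
    if model.name == "euclidean":
        coords = rng.uniform(0.0, scale, size=(n, dim))
    elif model.name == "spherical":
        r = model.curvature
        raw = rng.standard_normal(size=(n, dim))
        coords = r * raw / np.linalg.norm(raw, axis=1)[:, None]
    elif model.name == "hyperbolic":
        if dim != 2:
            raise ValueError("hyperbolic sampling is implemented for dim=2 only")
        big_r = scale
        theta = rng.uniform(0.0, 2.0 * np.pi, size=n)
        # radius CDF (cosh r - 1)/(cosh R - 1), inverted
        u = rng.uniform(0.0, 1.0, size=n)
        native_r = np.arccosh(1.0 + u * (np.cosh(big_r) - 1.0))
        ball_r = np.tanh(native_r / 2.0)
        coords = np.column_stack((ball_r * np.cos(theta), ball_r * np.sin(theta)))
    else:  # pragma: no cover - MetricModel validates names
        raise ValueError(f"unsupported model {model.name!r}")
    dist = pairwise_model_distances(coords, model)
    return PlantedConfiguration(
        model=model,
        coords=coords,
        true_distances=dist,
        seed=seed,
        params={"n": n, "dim": dim, "scale": scale},
    )


def planted_dissimilarity(
    cfg: PlantedConfiguration,
    noise_sigma: float = 0.0,
    seed: int | None = None,
) -> DissimilarityMatrix:
    """Exact planted distances, optionally with multiplicative log-normal noise.

    Noise preserves positivity and symmetry; the diagonal stays zero.
    """
    d = cfg.true_distances.copy()
    if noise_sigma > 0:
        rng = np.random.default_rng(cfg.seed if seed is None else seed)
        n = d.shape[0]
        factors = rng.lognormal(mean=0.0, sigma=noise_sigma, size=(n, n))
        factors = np.triu(factors, k=1)
        factors = factors + factors.T
        d = d * factors
        np.fill_diagonal(d, 0.0)
    return DissimilarityMatrix(values=d)


def geometric_graph(cfg: PlantedConfiguration, threshold: float) -> GeneNetwork:
    """Threshold graph: edge (i, j) iff the true distance is below threshold.

    Node identifiers are "n0001", "n0002", ... in point order.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    n = cfg.true_distances.shape[0]
    ids = [f"n{i + 1:04d}" for i in range(n)]
    edges = [
        (ids[i], ids[j])
        for i in range(n)
        for j in range(i + 1, n)
        if cfg.true_distances[i, j] < threshold
    ]
    if not edges:
        raise ValueError("threshold graph has no edges")
    return network_from_edges(edges)


@dataclass
class FixtureGraph:
    """A tiny graph with closed-form expected spring-model values.

    ``expected_stiffness`` is derived from the 1/(m_i m_j) closed form of the
    per-component one-dimensional nullspace, independently of the SVD path.
    """

    network: GeneNetwork
    expected_masses: np.ndarray
    expected_kernel_dim: int
    expected_stiffness: np.ndarray


def _closed_form_stiffness(g: GeneNetwork) -> tuple[np.ndarray, int]:
    """Per-component closed form: within a component, k_ij = (1/(m_i m_j)) /
    sum_l 1/m_l^2; zero across components.  Assumes no isolated nodes.
    """
    n = g.n_nodes
    masses = g.degrees()
    # connected components by union-find
    parent = list(range(n))

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for i, j in g.edges:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[ri] = rj
    roots = [find(i) for i in range(n)]
    k = np.zeros((n, n))
    comps = set(roots)
    for root in comps:
        members = [i for i in range(n) if roots[i] == root]
        inv = 1.0 / masses[members]
        v = inv / np.linalg.norm(inv)
        for a, i in enumerate(members):
            for b, j in enumerate(members):
                k[i, j] = v[a] * v[b]
    return k, len(comps)


def fixture_graphs() -> dict[str, FixtureGraph]:
    """Named tiny graphs with precomputed expected spring-model values."""
    raw: dict[str, list[tuple[str, str]]] = {
        "p2": [("a", "b")],
        "triangle": [("a", "b"), ("b", "c"), ("a", "c")],
        "star3": [("hub", "leaf1"), ("hub", "leaf2"), ("hub", "leaf3")],
        "path5": [("a", "b"), ("b", "c"), ("c", "d"), ("d", "e")],
        "two_cliques": _clique_edges("x", 10) + _clique_edges("y", 10),
        "bridged_cliques": (
            _clique_edges("x", 10) + _clique_edges("y", 10) + [("x01", "y01")]
        ),
    }
    out: dict[str, FixtureGraph] = {}
    for name, edges in raw.items():
        g = network_from_edges(edges)
        k, ncomp = _closed_form_stiffness(g)
        out[name] = FixtureGraph(
            network=g,
            expected_masses=g.degrees(),
            expected_kernel_dim=ncomp,
            expected_stiffness=k,
        )
    return out


def _clique_edges(prefix: str, size: int) -> list[tuple[str, str]]:
    ids = [f"{prefix}{i + 1:02d}" for i in range(size)]
    return [(ids[i], ids[j]) for i in range(size) for j in range(i + 1, size)]
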