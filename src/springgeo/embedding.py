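"""Embeddings of a dissimilarity matrix into Euclidean, hyperbolic
(Poincare ball), and spherical model spaces, with raw residual-sum-of-squares
stress and minimum-stress geometry selection.

Euclidean embedding is classical (Torgerson) multidimensional scaling.
Hyperbolic embedding uses a strain-minimizing initialization (eigendecomposing
``cosh(sqrt(kappa) * D)``, hyperboloid components from the extreme eigenpairs)
followed by quasi-Newton stress minimization over ball coordinates.
Spherical embedding optimizes the curvature radius ``r`` by minimizing the
magnitude of the smallest eigenvalue of ``Z(r) = r^2 cos(D / r)`` and factors
``Z(r*)``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.optimize

from .spring_model import DissimilarityMatrix

logger = logging.getLogger(__name__)

_MODEL_NAMES = ("euclidean", "hyperbolic", "spherical")
_BALL_MAX_NORM = 1.0 - 1e-6


@dataclass(frozen=True)
class MetricModel:
    """One of the three isotropic model spaces.

    ``curvature`` is the curvature magnitude kappa for the hyperbolic model
    and the sphere radius r for the spherical model; it is ignored for the
    Euclidean model.
    """

    name: str
    curvature: float = 1.0

    def __post_init__(self) -> None:
        if self.name not in _MODEL_NAMES:
            raise ValueError(f"unknown model {self.name!r}; expected one of {_MODEL_NAMES}")
        if self.curvature <= 0:
            raise ValueError("curvature parameter must be positive")


EUCLIDEAN = MetricModel("euclidean")
HYPERBOLIC = MetricModel("hyperbolic")
SPHERICAL = MetricModel("spherical")


@dataclass
class EmbeddingResult:
    """Coordinates of the nodes in one model space plus the achieved stress.

    ``radial`` is the Euclidean norm of the ball coordinates for hyperbolic
    embeddings, the norm from the centroid for Euclidean embeddings, and
    ``None`` for spherical embeddings.
    """

    coordinates: np.ndarray
    model: MetricModel
    dimension: int
    stress: float
    radial: np.ndarray | None = None
    normalized_stress: float | None = None
    node_ids: tuple[str, ...] | None = None


@dataclass
class StressTable:
    """Stress per (model, dimension) and the minimum-stress combination."""

    rows: list[tuple[str, int, float]] = field(default_factory=list)

    @property
    def best(self) -> tuple[str, int]:
        if not self.rows:
            raise ValueError("empty stress table")
        name, dim, _ = min(self.rows, key=lambda r: r[2])
        return name, dim

    @property
    def best_stress(self) -> float:
        return min(r[2] for r in self.rows)


def _as_matrix(d: DissimilarityMatrix | np.ndarray) -> tuple[np.ndarray, tuple[str, ...] | None]:
    if isinstance(d, DissimilarityMatrix):
        return d.values, d.node_ids
    d = np.asarray(d, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("dissimilarity input must be a square matrix")
    return d, None


# ---------------------------------------------------------------------------
# distances


def metric_distance(u: np.ndarray, v: np.ndarray, model: MetricModel) -> float:
    """Geodesic distance between two points in the given model space."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise ValueError("points must have the same dimension")
    if model.name == "euclidean":
        return float(np.linalg.norm(u - v))
    if model.name == "hyperbolic":
        nu, nv = np.linalg.norm(u), np.linalg.norm(v)
        if nu >= 1.0 or nv >= 1.0:
            raise ValueError("hyperbolic points must lie strictly inside the unit ball")
        num = 2.0 * float(np.sum((u - v) ** 2))
        den = (1.0 - nu**2) * (1.0 - nv**2)
        arg = 1.0 + num / den
        return float(np.arccosh(max(arg, 1.0)) / np.sqrt(model.curvature))
    # spherical
    r = model.curvature
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if abs(nu - r) > 1e-6 * r or abs(nv - r) > 1e-6 * r:
        raise ValueError("spherical points must lie on the radius-r sphere")
    cosang = np.clip(float(np.dot(u, v)) / r**2, -1.0, 1.0)
    return float(r * np.arccos(cosang))


def poincare_disk_distance(a: complex, b: complex) -> float:
    """Hyperbolic distance between two points of the unit disk, complex form:
    ``log((|1 - conj(a) b| + |b - a|) / (|1 - conj(a) b| - |b - a|))``.
    """
    a, b = complex(a), complex(b)
    if abs(a) >= 1.0 or abs(b) >= 1.0:
        raise ValueError("disk points must have modulus < 1")
    p = abs(1.0 - np.conj(a) * b)
    q = abs(b - a)
    return float(np.log((p + q) / (p - q)))


def pairwise_model_distances(coords: np.ndarray, model: MetricModel) -> np.ndarray:
    """All-pairs geodesic distance matrix for points in a model space."""
    x = np.asarray(coords, dtype=float)
    if model.name == "euclidean":
        diff = x[:, None, :] - x[None, :, :]
        return np.sqrt(np.sum(diff**2, axis=-1))
    if model.name == "hyperbolic":
        sq = np.sum(x**2, axis=1)
        if np.any(sq >= 1.0):
            raise ValueError("hyperbolic points must lie strictly inside the unit ball")
        gram = x @ x.T
        dist2 = sq[:, None] + sq[None, :] - 2.0 * gram
        denom = (1.0 - sq)[:, None] * (1.0 - sq)[None, :]
        arg = 1.0 + 2.0 * np.clip(dist2, 0.0, None) / denom
        d = np.arccosh(np.clip(arg, 1.0, None)) / np.sqrt(model.curvature)
        np.fill_diagonal(d, 0.0)
        return d
    r = model.curvature
    cosang = np.clip((x @ x.T) / r**2, -1.0, 1.0)
    d = r * np.arccos(cosang)
    np.fill_diagonal(d, 0.0)
    return d


# ---------------------------------------------------------------------------
# stress


def stress_from_matrices(d_in: np.ndarray, d_emb: np.ndarray) -> float:
    """Raw residual sum of squares over unordered pairs (no normalization)."""
    iu = np.triu_indices(d_in.shape[0], k=1)
    return float(np.sum((d_in[iu] - d_emb[iu]) ** 2))


def embedding_stress(
    d: DissimilarityMatrix | np.ndarray, emb: EmbeddingResult
) -> float:
    """Recompute the stress of an embedding against an input dissimilarity."""
    values, _ = _as_matrix(d)
    if values.shape[0] != emb.coordinates.shape[0]:
        raise ValueError("dissimilarity and embedding node counts differ")
    d_emb = pairwise_model_distances(emb.coordinates, emb.model)
    return stress_from_matrices(values, d_emb)


def _finish(
    coords: np.ndarray,
    model: MetricModel,
    p: int,
    d_in: np.ndarray,
    node_ids: tuple[str, ...] | None,
) -> EmbeddingResult:
    d_emb = pairwise_model_distances(coords, model)
    stress = stress_from_matrices(d_in, d_emb)
    iu = np.triu_indices(d_in.shape[0], k=1)
    total = float(np.sum(d_in[iu] ** 2))
    if model.name == "hyperbolic":
        radial = np.linalg.norm(coords, axis=1)
    elif model.name == "euclidean":
        radial = np.linalg.norm(coords - coords.mean(axis=0), axis=1)
    else:
        radial = None
    return EmbeddingResult(
        coordinates=coords,
        model=model,
        dimension=p,
        stress=stress,
        radial=radial,
        normalized_stress=stress / total if total > 0 else None,
        node_ids=node_ids,
    )


# ---------------------------------------------------------------------------
# Euclidean: classical MDS


def _euclidean_stress_grad(
    flat: np.ndarray, d_in: np.ndarray, n: int, p: int
) -> tuple[float, np.ndarray]:
    x = flat.reshape(n, p)
    diff = x[:, None, :] - x[None, :, :]
    delta = np.sqrt(np.sum(diff**2, axis=-1))
    resid = delta - d_in
    iu = np.triu_indices(n, k=1)
    stress = float(np.sum(resid[iu] ** 2))
    safe = np.where(delta > 0, delta, 1.0)
    w = 2.0 * resid / safe
    np.fill_diagonal(w, 0.0)
    grad = w.sum(axis=1)[:, None] * x - w @ x
    return stress, grad.ravel()


def embed_euclidean(
    d: DissimilarityMatrix | np.ndarray,
    p: int,
    refine: bool = False,
    max_iter: int = 500,
    gtol: float = 1e-8,
) -> EmbeddingResult:
    """Classical (Torgerson) multidimensional scaling into R^p.

    Double-centers ``-D^2 / 2``, eigendecomposes, and keeps the top ``p``
    eigenpairs; negative eigenvalues are clamped to zero (count logged).
    With ``refine=True`` the configuration is polished by quasi-Newton stress
    minimization (the iterative stress-descent view of metric scaling), which
    keeps the stress criterion comparable with the refined hyperbolic
    embedding during geometry selection.
    """
    values, node_ids = _as_matrix(d)
    n = values.shape[0]
    if not 2 <= p < n:
        raise ValueError(f"dimension p must satisfy 2 <= p < n (p={p}, n={n})")
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (values**2) @ j
    b = 0.5 * (b + b.T)
    eigvals, eigvecs = np.linalg.eigh(b)
    order = np.argsort(eigvals)[::-1][:p]
    lam = eigvals[order]
    n_neg = int(np.sum(lam < 0))
    if n_neg:
        logger.info("classical MDS: clamped %d negative eigenvalue(s)", n_neg)
    lam = np.clip(lam, 0.0, None)
    coords = eigvecs[:, order] * np.sqrt(lam)[None, :]
    if refine:
        res = scipy.optimize.minimize(
            _euclidean_stress_grad,
            coords.ravel(),
            args=(values, n, p),
            jac=True,
            method="L-BFGS-B",
            options={"maxiter": max_iter, "gtol": gtol},
        )
        coords = res.x.reshape(n, p)
    return _finish(coords, EUCLIDEAN, p, values, node_ids)


# ---------------------------------------------------------------------------
# hyperbolic: strain-minimizing init + stress refinement


def _hyperbolic_init(values: np.ndarray, p: int, kappa: float) -> np.ndarray:
    """Strain-minimizing ('hydra') initial ball coordinates.

    Eigendecompose ``Y = cosh(sqrt(kappa) D)``; the leading eigenpair gives
    the time-like hyperboloid coordinate (entrywise absolute value, clamped
    at 1), the p most-negative eigenpairs the spatial directions.
    """
    n = values.shape[0]
    y = np.cosh(np.sqrt(kappa) * values)
    eigvals, eigvecs = np.linalg.eigh(y)
    lam_max = eigvals[-1]
    x0 = np.sqrt(max(lam_max, 0.0)) * np.abs(eigvecs[:, -1])
    x0 = np.clip(x0, 1.0, None)

    neg_order = np.argsort(eigvals)[:p]
    spatial = np.zeros((n, p))
    n_neg = 0
    for col, idx in enumerate(neg_order):
        if eigvals[idx] < 0:
            spatial[:, col] = np.sqrt(-eigvals[idx]) * eigvecs[:, idx]
            n_neg += 1
    if n_neg < p:
        warnings.warn(
            f"hyperbolic init: only {n_neg} negative eigenvalue(s) for "
            f"p={p}; padding spatial directions with zeros",
            RuntimeWarning,
            stacklevel=3,
        )
    norms = np.linalg.norm(spatial, axis=1)
    directions = np.zeros_like(spatial)
    nz = norms > 0
    directions[nz] = spatial[nz] / norms[nz, None]
    directions[~nz, 0] = 1.0  # deterministic direction for degenerate rows
    radial = np.sqrt((x0 - 1.0) / (x0 + 1.0))
    coords = radial[:, None] * directions
    return _project_into_ball(coords)


def _project_into_ball(coords: np.ndarray, max_norm: float = _BALL_MAX_NORM) -> np.ndarray:
    norms = np.linalg.norm(coords, axis=1)
    out = coords.copy()
    mask = norms > max_norm
    if np.any(mask):
        out[mask] = coords[mask] * (max_norm / norms[mask])[:, None]
    return out


def _hyperbolic_stress_grad(
    flat: np.ndarray, d_in: np.ndarray, n: int, p: int, kappa: float
) -> tuple[float, np.ndarray]:
    """Stress and analytic gradient w.r.t. Poincare-ball coordinates."""
    x = _project_into_ball(flat.reshape(n, p))
    sq = np.sum(x**2, axis=1)
    b = 1.0 - sq  # > 0 inside the ball
    gram = x @ x.T
    dist2 = np.clip(sq[:, None] + sq[None, :] - 2.0 * gram, 0.0, None)
    denom = b[:, None] * b[None, :]
    g = 1.0 + 2.0 * dist2 / denom
    sk = np.sqrt(kappa)
    delta = np.arccosh(np.clip(g, 1.0, None)) / sk
    np.fill_diagonal(delta, 0.0)

    resid = delta - d_in
    iu = np.triu_indices(n, k=1)
    stress = float(np.sum(resid[iu] ** 2))

    root = np.sqrt(np.clip(g**2 - 1.0, 1e-24, None))
    w = 2.0 * resid / (root * sk)
    np.fill_diagonal(w, 0.0)

    # d g_ij / d x_i = 4 (x_i - x_j) / (b_i b_j) + 4 dist2_ij x_i / (b_i^2 b_j)
    pmat = 4.0 * w / denom
    row_p = pmat.sum(axis=1)
    grad = row_p[:, None] * x - pmat @ x
    s = 4.0 * np.sum(w * dist2 / (b[:, None] ** 2 * b[None, :]), axis=1)
    grad += s[:, None] * x
    return stress, grad.ravel()


def embed_hyperbolic(
    d: DissimilarityMatrix | np.ndarray,
    p: int,
    kappa: float = 1.0,
    refine: bool = True,
    max_iter: int = 500,
    gtol: float = 1e-8,
) -> EmbeddingResult:
    """Embed into the p-dimensional Poincare ball of curvature -kappa.

    Strain-minimizing eigendecomposition initialization, optionally followed
    by L-BFGS-B stress minimization with coordinates projected to stay
    strictly inside the unit ball.
    """
    values, node_ids = _as_matrix(d)
    n = values.shape[0]
    if p < 2:
        raise ValueError("dimension p must be >= 2")
    if kappa <= 0:
        raise ValueError("curvature kappa must be positive")
    coords = _hyperbolic_init(values, p, kappa)
    if refine and n >= 2:
        res = scipy.optimize.minimize(
            _hyperbolic_stress_grad,
            coords.ravel(),
            args=(values, n, p, kappa),
            jac=True,
            method="L-BFGS-B",
            options={"maxiter": max_iter, "gtol": gtol},
        )
        coords = _project_into_ball(res.x.reshape(n, p))
    model = MetricModel("hyperbolic", curvature=kappa)
    return _finish(coords, model, p, values, node_ids)


# ---------------------------------------------------------------------------
# spherical: curvature-radius search + eigendecomposition


def _min_eigval(z: np.ndarray) -> float:
    return float(np.linalg.eigvalsh(z)[0])


def embed_spherical(
    d: DissimilarityMatrix | np.ndarray,
    p: int,
    n_grid: int = 60,
) -> EmbeddingResult:
    """Embed onto a sphere of optimized radius.

    The radius ``r`` is searched over ``[max(D)/pi (1 + eps), 10 max(D)]``
    (log grid + bounded scalar refinement) minimizing ``|lambda_min(Z(r))|``
    with ``Z(r) = r^2 cos(D / r)``.  At the optimum, ``Z(r*)`` is
    eigendecomposed, the top-p non-negative eigenpairs give coordinates, and
    each row is projected onto the radius-r* sphere.
    """
    values, node_ids = _as_matrix(d)
    n = values.shape[0]
    if p < 2:
        raise ValueError("dimension p must be >= 2")
    dmax = float(values.max())
    if dmax <= 0:
        raise ValueError("dissimilarity matrix has no positive entries")

    r_lo = (dmax / np.pi) * (1.0 + 1e-9) + 1e-12
    r_hi = 10.0 * dmax

    def objective(r: float) -> float:
        z = r**2 * np.cos(values / r)
        if not np.all(np.isfinite(z)):
            raise ValueError("non-finite entries in Z(r)")
        return abs(_min_eigval(z))

    grid = np.geomspace(r_lo, r_hi, n_grid)
    obj = np.array([objective(r) for r in grid])
    best = int(np.argmin(obj))
    if best in (0, n_grid - 1):
        warnings.warn(
            "spherical radius search hit the bracket boundary; the optimum "
            "may lie outside the search interval",
            RuntimeWarning,
            stacklevel=2,
        )
        lo = grid[max(best - 1, 0)]
        hi = grid[min(best + 1, n_grid - 1)]
    else:
        lo, hi = grid[best - 1], grid[best + 1]
    res = scipy.optimize.minimize_scalar(
        objective, bounds=(lo, hi), method="bounded",
        options={"xatol": 1e-8 * dmax},
    )
    r_star = float(res.x)

    z = r_star**2 * np.cos(np.clip(values / r_star, 0.0, np.pi))
    eigvals, eigvecs = np.linalg.eigh(z)
    order = np.argsort(eigvals)[::-1][:p]
    lam = np.clip(eigvals[order], 0.0, None)
    coords = eigvecs[:, order] * np.sqrt(lam)[None, :]
    norms = np.linalg.norm(coords, axis=1)
    nz = norms > 0
    coords[nz] = coords[nz] * (r_star / norms[nz, None])
    if np.any(~nz):  # degenerate rows pinned to a pole, deterministically
        coords[~nz, 0] = r_star
    model = MetricModel("spherical", curvature=r_star)
    return _finish(coords, model, p, values, node_ids)


# ---------------------------------------------------------------------------
# geometry selection


def select_geometry(
    d: DissimilarityMatrix | np.ndarray,
    dims: list[int] | None = None,
    models: list[str] | None = None,
    kappa: float = 1.0,
    refine: bool = True,
) -> StressTable:
    """Stress of every (model, dimension) combination; best = minimum stress.

    Failed embeddings are recorded as missing rows with a warning; the sweep
    never aborts.
    """
    values, _ = _as_matrix(d)
    if dims is None:
        dims = list(range(3, 11))
    if not dims:
        raise ValueError("dims must be non-empty")
    if models is None:
        models = list(_MODEL_NAMES)
    table = StressTable()
    for name in models:
        for p in dims:
            try:
                if name == "euclidean":
                    emb = embed_euclidean(values, p, refine=refine)
                elif name == "hyperbolic":
                    emb = embed_hyperbolic(values, p, kappa=kappa, refine=refine)
                elif name == "spherical":
                    emb = embed_spherical(values, p)
                else:
                    raise ValueError(f"unknown model {name!r}")
            except Exception as exc:  # noqa: BLE001 - sweep must not abort
                warnings.warn(
                    f"embedding failed for model={name}, p={p}: {exc}",
                    RuntimeWarning,
                    stacklevel=2,
                )
                continue
            table.rows.append((name, p, emb.stress))
    return table
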