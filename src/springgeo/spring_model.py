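"""Spring-network model: vibrational centrality, mass-weighted incidence,
nullspace-derived stiffness, and the stiffness-based dissimilarity matrix.

The network is conceived as point masses (nodes, mass = total degree) joined
by springs (edges).  At mechanical equilibrium the all-pairs stiffness matrix
is built from an orthonormal basis ``N`` of the nullspace of ``C^T`` (``C``
the mass-weighted oriented incidence matrix) as the projector ``K = N N^T``.
Off-diagonal stiffness is min-max rescaled to [0, 1] and converted to a
dissimilarity ``d_ij = 1 / (1 + k~_ij)`` with a zero diagonal.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.linalg

from .network_io import GeneNetwork

logger = logging.getLogger(__name__)

#: relative singular-value threshold used for numerical rank / nullspace
DEFAULT_NULLSPACE_TOL = 1e-10


@dataclass
class VibrationalCentrality:
    """Node displacement amplitudes under a thermal bath.

    ``displacement[i] = sqrt((T / k0) * Lplus[i, i])`` where ``Lplus`` is the
    Moore-Penrose pseudoinverse of the unweighted graph Laplacian.
    """

    displacement: np.ndarray
    temperature: float = 1.0
    common_stiffness: float = 1.0


@dataclass
class StiffnessMatrix:
    """Dense symmetric node-by-node spring stiffness.

    ``raw`` is the stiffness as computed; ``rescaled`` (filled by
    :func:`rescale_stiffness`) holds the off-diagonal min-max rescaling with a
    zero diagonal.  ``kernel_basis`` is the orthonormal nullspace basis used
    to build ``raw`` in the equilibrium case (``None`` for the
    non-equilibrium variant).
    """

    raw: np.ndarray
    kernel_dim: int = 0
    kernel_basis: np.ndarray | None = None
    rescaled: np.ndarray | None = None
    node_ids: tuple[str, ...] | None = None


@dataclass
class DissimilarityMatrix:
    """Symmetric zero-diagonal matrix consumed by every embedding."""

    values: np.ndarray
    node_ids: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("dissimilarity matrix must be square")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("dissimilarity matrix must be symmetric")
        if not np.allclose(np.diag(v), 0.0, atol=1e-12):
            raise ValueError("dissimilarity matrix must have a zero diagonal")
        self.values = v

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def to_csv(self, path: str | Path) -> None:
        write_square_csv(self.values, path, node_ids=self.node_ids)

    @classmethod
    def from_csv(cls, path: str | Path) -> "DissimilarityMatrix":
        values, node_ids = read_square_csv(path)
        return cls(values=values, node_ids=node_ids)


def write_square_csv(
    matrix: np.ndarray, path: str | Path, node_ids: tuple[str, ...] | None = None
) -> None:
    """Write a square matrix as CSV with a header row of node identifiers."""
    n = matrix.shape[0]
    ids = node_ids if node_ids is not None else tuple(f"n{i:04d}" for i in range(n))
    df = pd.DataFrame(matrix, index=list(ids), columns=list(ids))
    df.to_csv(path, float_format="%.17g")


def read_square_csv(path: str | Path) -> tuple[np.ndarray, tuple[str, ...]]:
    df = pd.read_csv(path, index_col=0)
    return df.to_numpy(dtype=float), tuple(str(c) for c in df.columns)


def vibrational_centrality(
    g: GeneNetwork, temperature: float = 1.0, k0: float = 1.0
) -> VibrationalCentrality:
    """Displacement amplitude of each node in a thermal bath of temperature T.

    Uses the pseudoinverse of the unweighted Laplacian; works per connected
    component (the pseudoinverse is block-diagonal on components).
    """
    if temperature <= 0 or k0 <= 0:
        raise ValueError("temperature and common stiffness must be positive")
    if g.n_nodes == 0:
        raise ValueError("empty graph")
    adj = g.adjacency_matrix()
    lap = np.diag(adj.sum(axis=1)) - adj
    lplus = np.linalg.pinv(lap, hermitian=True)
    diag = np.clip(np.diag(lplus), 0.0, None)
    disp = np.sqrt((temperature / k0) * diag)
    return VibrationalCentrality(
        displacement=disp, temperature=temperature, common_stiffness=k0
    )


def weighted_incidence(incidence: np.ndarray, masses: np.ndarray) -> np.ndarray:
    """Mass-weighted incidence ``C[i, e] = m_i * A[i, e]`` (row scaling)."""
    incidence = np.asarray(incidence, dtype=float)
    masses = np.asarray(masses, dtype=float)
    if incidence.shape[0] != masses.shape[0]:
        raise ValueError("incidence rows and mass vector length differ")
    incident = np.any(incidence != 0.0, axis=1)
    if np.any(masses[incident] <= 0):
        raise ValueError("node with incident edge has non-positive mass")
    return masses[:, None] * incidence


def stiffness_equilibrium(
    weighted: np.ndarray, tol: float = DEFAULT_NULLSPACE_TOL,
    node_ids: tuple[str, ...] | None = None,
) -> StiffnessMatrix:
    """All-pairs stiffness from the nullspace of ``C^T`` at equilibrium.

    An orthonormal basis ``N`` of ``{v : C^T v = 0}`` (singular values below
    ``tol * sigma_max`` treated as zero) yields ``K = N N^T``; for a connected
    graph the kernel is spanned by ``v_i = 1 / m_i`` and ``K`` is rank one.
    """
    weighted = np.asarray(weighted, dtype=float)
    if weighted.size == 0 or not np.any(weighted):
        raise ValueError("weighted incidence matrix is zero")
    basis = scipy.linalg.null_space(weighted.T, rcond=tol)
    if basis.shape[1] == 0:
        raise ValueError(
            "empty nullspace of C^T: no equilibrium stiffness exists "
            "(unexpected for an oriented incidence matrix)"
        )
    residual = np.max(np.abs(weighted.T @ basis))
    logger.debug("nullspace dim=%d, max residual |C^T v| = %.3e",
                 basis.shape[1], residual)
    k = basis @ basis.T
    return StiffnessMatrix(
        raw=k, kernel_dim=basis.shape[1], kernel_basis=basis, node_ids=node_ids
    )


def stiffness_nonequilibrium(
    weighted: np.ndarray,
    node_forces: np.ndarray,
    delta_x: VibrationalCentrality | np.ndarray,
) -> StiffnessMatrix:
    """Stiffness when node forces do not balance.

    Solves ``C^T K diag(dx) = F`` in the least-squares sense,
    ``K = pinv(C^T) @ F @ diag(dx)^-1``, then symmetrizes.  ``C^T`` is always
    rank deficient (rank of an oriented incidence is at most n-1), so the
    Moore-Penrose pseudoinverse is used and a warning emitted.  A per-node
    force vector is broadcast across the edge-indexed rows of the system.
    """
    weighted = np.asarray(weighted, dtype=float)
    n, m = weighted.shape
    dx = (
        delta_x.displacement
        if isinstance(delta_x, VibrationalCentrality)
        else np.asarray(delta_x, dtype=float)
    )
    if np.any(dx == 0):
        raise ValueError(
            "delta_x is invertible only if all its diagonal entries are "
            "non-zero; got a zero displacement"
        )
    forces = np.asarray(node_forces, dtype=float)
    if forces.ndim == 1:
        if forces.shape[0] != n:
            raise ValueError("node force vector length must equal node count")
        forces = np.broadcast_to(forces, (m, n))
    elif forces.shape != (m, n):
        raise ValueError(f"force matrix must have shape ({m}, {n})")
    warnings.warn(
        "C^T is singular; using the Moore-Penrose pseudoinverse "
        "(least-squares solution)",
        RuntimeWarning,
        stacklevel=2,
    )
    k = np.linalg.pinv(weighted.T) @ forces @ np.diag(1.0 / dx)
    k = 0.5 * (k + k.T)
    return StiffnessMatrix(raw=k, kernel_dim=0, kernel_basis=None)


def rescale_stiffness(k: StiffnessMatrix) -> StiffnessMatrix:
    """Min-max rescale the off-diagonal stiffness into [0, 1].

    Degenerate case (all off-diagonal values equal): every rescaled value is
    set to 1 with a warning.  The rescaled diagonal is 0.
    """
    raw = k.raw
    n = raw.shape[0]
    off_mask = ~np.eye(n, dtype=bool)
    off = raw[off_mask]
    lo, hi = off.min(), off.max()
    rescaled = np.zeros_like(raw)
    if np.isclose(hi, lo):
        warnings.warn(
            "degenerate stiffness rescale: all off-diagonal values equal; "
            "setting rescaled stiffness to 1",
            RuntimeWarning,
            stacklevel=2,
        )
        rescaled[off_mask] = 1.0
    else:
        rescaled[off_mask] = (raw[off_mask] - lo) / (hi - lo)
    return dataclasses.replace(k, rescaled=rescaled)


def stiffness_to_dissimilarity(k: StiffnessMatrix) -> DissimilarityMatrix:
    """Dissimilarity ``d_ij = 1 / (1 + k~_ij)`` from rescaled stiffness.

    The diagonal is forced to zero (required by every embedding method).
    """
    if k.rescaled is None:
        raise ValueError("call rescale_stiffness first")
    d = 1.0 / (1.0 + k.rescaled)
    np.fill_diagonal(d, 0.0)
    return DissimilarityMatrix(values=d, node_ids=k.node_ids)
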