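"""Spatial proximity kernels between (or within) cell populations.

The workhorse is the isotropic Gaussian kernel on Euclidean distance,
``K_ij = exp(-(d_ij / sigma)^2 / 2)``.  Two variants extend it: a
morphology-aware filter that reclassifies Euclidean-close but geodesically
distant pairs as non-local (for tissues with folds, lumens or gaps), and an
anisotropic kernel with separate bandwidths along and across a user-chosen
axis (for tissues organized along a known anatomical direction).

Distances are taken in the input coordinate units; no internal rescaling is
performed, so bandwidths must be specified in those same units.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import scipy.io
import scipy.sparse as sp
from scipy.sparse.csgraph import shortest_path
from scipy.spatial.distance import cdist
from sklearn.neighbors import kneighbors_graph

from .exceptions import ParameterError

logger = logging.getLogger(__name__)

#: kernels denser than this are kept dense; sparser ones stored as CSR
SPARSE_DENSITY_THRESHOLD = 0.25
#: multiple of the max observed distance used to mark non-local pairs
SENTINEL_FACTOR = 1e6


@dataclass
class SpatialKernel:
    """Nonnegative proximity weights between a source and a target population."""

    weights: np.ndarray | sp.spmatrix  # (ns, nt), entries in [0, 1]
    bandwidth: float
    source_type: str = ""
    target_type: str = ""
    cutoff_quantile: float | None = None

    @property
    def shape(self) -> tuple[int, int]:
        return self.weights.shape

    @property
    def is_sparse(self) -> bool:
        return sp.issparse(self.weights)

    def dense(self) -> np.ndarray:
        return self.weights.toarray() if self.is_sparse else self.weights

    def matvec(self, v: np.ndarray) -> np.ndarray:
        """K @ v."""
        return np.asarray(self.weights @ v)

    def rmatvec(self, v: np.ndarray) -> np.ndarray:
        """K.T @ v."""
        return np.asarray(self.weights.T @ v)

    def matmat(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(self.weights @ X)

    def rmatmat(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(self.weights.T @ X)

    def row_sums(self) -> np.ndarray:
        return np.asarray(self.weights.sum(axis=1)).ravel()

    def col_sums(self) -> np.ndarray:
        return np.asarray(self.weights.sum(axis=0)).ravel()

    def transpose(self) -> "SpatialKernel":
        return SpatialKernel(
            weights=self.weights.T,
            bandwidth=self.bandwidth,
            source_type=self.target_type,
            target_type=self.source_type,
            cutoff_quantile=self.cutoff_quantile,
        )

    def to_mtx(self, path: str | Path) -> None:
        """Export as a Matrix Market sparse file for inspection."""
        scipy.io.mmwrite(str(path), sp.coo_matrix(self.weights))


def _maybe_sparsify(W: np.ndarray) -> np.ndarray | sp.csr_matrix:
    density = np.count_nonzero(W) / W.size if W.size else 1.0
    if density < SPARSE_DENSITY_THRESHOLD:
        return sp.csr_matrix(W)
    return W


def _validate_coords(coords: np.ndarray, name: str) -> np.ndarray:
    coords = np.asarray(coords, dtype=float)
    if coords.size == 0:
        raise ParameterError(f"{name}: empty coordinate set")
    if coords.ndim != 2 or coords.shape[1] != 2:
        raise ParameterError(f"{name}: expected an (n, 2) coordinate matrix")
    if not np.all(np.isfinite(coords)):
        raise ParameterError(f"{name}: coordinates must be finite")
    return coords


def gaussian_kernel(
    coords_s: np.ndarray,
    coords_t: np.ndarray,
    sigma: float,
    cutoff_quantile: float | None = None,
    source_type: str = "",
    target_type: str = "",
    distances: np.ndarray | None = None,
) -> SpatialKernel:
    """Gaussian kernel on Euclidean (or precomputed, e.g. filtered) distances.

    With ``cutoff_quantile`` set, distances above that quantile of all
    pairwise distances receive weight 0 and the kernel is stored sparse when
    it pays off.
    """
    if sigma <= 0:
        raise ParameterError(f"sigma must be positive, got {sigma}")
    if distances is None:
        coords_s = _validate_coords(coords_s, "coords_s")
        coords_t = _validate_coords(coords_t, "coords_t")
        distances = cdist(coords_s, coords_t)
    W = np.exp(-0.5 * (distances / sigma) ** 2)
    if cutoff_quantile is not None:
        if not 0 < cutoff_quantile <= 1:
            raise ParameterError("cutoff_quantile must lie in (0, 1]")
        if cutoff_quantile < 1:
            thresh = np.quantile(distances, cutoff_quantile)
            W = np.where(distances > thresh, 0.0, W)
            W = _maybe_sparsify(W)
    return SpatialKernel(
        weights=W,
        bandwidth=float(sigma),
        source_type=source_type,
        target_type=target_type,
        cutoff_quantile=cutoff_quantile,
    )


def directional_kernel(
    coords_s: np.ndarray,
    coords_t: np.ndarray,
    sigma_parallel: float,
    sigma_perp: float,
    axis: np.ndarray,
    source_type: str = "",
    target_type: str = "",
) -> SpatialKernel:
    """Anisotropic Gaussian kernel with separate along-/across-axis bandwidths.

    ``weight = exp(-[(d_par/sigma_par)^2 + (d_perp/sigma_perp)^2] / 2)`` where
    ``d_par`` / ``d_perp`` are displacement components along and perpendicular
    to ``axis``.  Reduces to :func:`gaussian_kernel` when the bandwidths agree.
    """
    if sigma_parallel <= 0 or sigma_perp <= 0:
        raise ParameterError("bandwidths must be positive")
    axis = np.asarray(axis, dtype=float).ravel()
    norm = np.linalg.norm(axis)
    if axis.shape != (2,) or norm == 0:
        raise ParameterError("axis must be a nonzero 2-vector")
    u = axis / norm
    coords_s = _validate_coords(coords_s, "coords_s")
    coords_t = _validate_coords(coords_t, "coords_t")
    delta_x = coords_s[:, 0:1] - coords_t[None, :, 0].reshape(1, -1)
    delta_y = coords_s[:, 1:2] - coords_t[None, :, 1].reshape(1, -1)
    d_par = delta_x * u[0] + delta_y * u[1]
    d_perp = -delta_x * u[1] + delta_y * u[0]
    W = np.exp(-0.5 * ((d_par / sigma_parallel) ** 2 + (d_perp / sigma_perp) ** 2))
    return SpatialKernel(
        weights=W,
        bandwidth=float(max(sigma_parallel, sigma_perp)),
        source_type=source_type,
        target_type=target_type,
    )


def morphology_filtered_distances(
    coords: np.ndarray,
    k: int = 10,
    reclassify_factor: float = 2.0,
) -> np.ndarray:
    """Distance matrix with Euclidean-close but geodesically distant pairs removed.

    Geodesic distances are shortest paths on a k-nearest-neighbor graph with
    Euclidean edge weights.  A linear Euclidean-to-geodesic relation is fit on
    the graph's own edges (the local neighborhoods where the two coincide);
    pairs whose geodesic distance exceeds ``reclassify_factor`` times the
    fitted prediction are assigned a sentinel large distance, which drives
    their kernel weight to zero.  Pairs in disconnected graph components are
    always non-local (logged, not an error).
    """
    if k < 2:
        raise ParameterError("k must be at least 2")
    coords = _validate_coords(coords, "coords")
    n = coords.shape[0]
    dE = cdist(coords, coords)
    if n <= k:
        return dE
    graph = kneighbors_graph(coords, n_neighbors=min(k, n - 1), mode="distance")
    graph = graph.maximum(graph.T)  # symmetrize
    dG = shortest_path(graph, method="D", directed=False)
    sentinel = SENTINEL_FACTOR * dE.max()
    # fit geodesic ~ slope * euclidean on connected, local pairs (graph edges)
    gi, gj = graph.nonzero()
    x = dE[gi, gj]
    y = dG[gi, gj]
    slope = float(np.dot(x, y) / np.dot(x, x)) if np.dot(x, x) > 0 else 1.0
    finite = np.isfinite(dG)
    n_disconnected = int((~finite).sum() - 0)
    if n_disconnected:
        logger.info(
            "morphology filter: %d pairs in disconnected components marked non-local",
            n_disconnected // 2,
        )
    nonlocal_mask = ~finite | (dG > reclassify_factor * slope * dE + 1e-12)
    np.fill_diagonal(nonlocal_mask, False)
    df = dE.copy()
    df[nonlocal_mask] = sentinel
    return df
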