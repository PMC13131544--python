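"""Coordination metrics (NCorr, BSC) and kernel bandwidth selection.

NCorr is the kernel-normalized canonical correlation,

    NCorr = w_i' X_i' K X_j w_j / (||X_i w_i|| ||X_j w_j|| ||K||_s),

where ``||K||_s`` is the spectral norm of the kernel; dividing by it bounds
NCorr in [-1, 1] and makes values comparable across bandwidths, which is what
the bandwidth-selection rule exploits.  BSC (bidirectional spatial
correlation) is the symmetric average of two Pearson correlations between one
population's scores and the kernel-smoothed scores of the other; it is
bounded in [-1, 1] and reads like an ordinary correlation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .exceptions import (
    InsufficientSupportError,
    ParameterError,
    UndefinedMetricError,
)
from .kernels import SpatialKernel

#: default kernel-support threshold below which cells are excluded from BSC
DEFAULT_SUPPORT_THRESHOLD = 5e-2

_SPECTRAL_MAX_ITER = 100
_SPECTRAL_TOL = 1e-7


@dataclass
class CoordinationMetrics:
    """NCorr/BSC for one component and cell-type pair in one sample."""

    ncorr: float
    bsc: float
    component: int
    pair: tuple[str, str]
    sample_id: str


def spectral_norm(K: np.ndarray | sp.spmatrix | SpatialKernel) -> float:
    """Largest singular value via power iteration on K'K (works sparse or dense)."""
    W = K.weights if isinstance(K, SpatialKernel) else K
    nt = W.shape[1]
    v = np.ones(nt) / np.sqrt(nt)
    s = 0.0
    for _ in range(_SPECTRAL_MAX_ITER):
        u = np.asarray(W @ v).ravel()
        w = np.asarray(W.T @ u).ravel()  # (W'W) v
        norm = np.linalg.norm(w)
        if norm == 0:
            return 0.0
        v = w / norm
        s_new = np.linalg.norm(np.asarray(W @ v).ravel())
        if abs(s_new - s) <= _SPECTRAL_TOL * max(s_new, 1.0):
            return float(s_new)
        s = s_new
    return float(s)


def _scores(X_or_v: np.ndarray, w: np.ndarray | None) -> np.ndarray:
    v = np.asarray(X_or_v, dtype=float)
    if w is not None:
        v = v @ np.asarray(w, dtype=float)
    return v.ravel() if v.ndim > 1 and 1 in v.shape else v


def ncorr(
    Xi: np.ndarray,
    Xj: np.ndarray,
    kernel: SpatialKernel | np.ndarray,
    wi: np.ndarray | None = None,
    wj: np.ndarray | None = None,
    kernel_norm: float | None = None,
) -> float:
    """Kernel-normalized canonical correlation between two score vectors.

    ``Xi``/``Xj`` are either score vectors directly or embedding score
    matrices combined with weight vectors ``wi``/``wj``.  ``kernel_norm``
    short-circuits the spectral-norm computation when it is already known
    (bandwidth profiling evaluates many pairs against the same kernel).
    """
    K = kernel if isinstance(kernel, SpatialKernel) else SpatialKernel(np.asarray(kernel, float), 1.0)
    vi = _scores(Xi, wi)
    vj = _scores(Xj, wj)
    if vi.shape[0] != K.shape[0] or vj.shape[0] != K.shape[1]:
        raise ParameterError(
            f"dimension mismatch: kernel {K.shape}, scores {vi.shape[0]}/{vj.shape[0]}"
        )
    ni, nj = np.linalg.norm(vi), np.linalg.norm(vj)
    if ni == 0 or nj == 0:
        raise UndefinedMetricError("zero-norm score vector")
    if kernel_norm is None:
        kernel_norm = spectral_norm(K)
    if kernel_norm == 0:
        raise UndefinedMetricError("kernel has zero spectral norm")
    return float(vi @ K.matvec(vj) / (ni * nj * kernel_norm))


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise UndefinedMetricError("zero-variance vector in Pearson correlation")
    return float(a @ b / (na * nb))


def bsc(
    vi: np.ndarray,
    vj: np.ndarray,
    kernel: SpatialKernel | np.ndarray,
    support_threshold: float = DEFAULT_SUPPORT_THRESHOLD,
) -> float:
    """Bidirectional spatial correlation between two populations' scores.

    ``BSC = [rho(smooth(v_i), v_j) + rho(v_i, smooth(v_j))] / 2`` with Pearson
    rho, where ``smooth`` is the kernel-weighted mean of the partner
    population's scores (row/column sums normalize the raw kernel products so
    the metric is invariant to affine transforms a*v + b, a > 0, like an
    ordinary correlation).  Cells whose kernel row (source side) or column
    (target side) sum falls below ``support_threshold`` are excluded first;
    near-isolated cells otherwise make the smoothed scores unstable.
    """
    K = kernel if isinstance(kernel, SpatialKernel) else SpatialKernel(np.asarray(kernel, float), 1.0)
    vi = np.asarray(vi, dtype=float).ravel()
    vj = np.asarray(vj, dtype=float).ravel()
    if vi.shape[0] != K.shape[0] or vj.shape[0] != K.shape[1]:
        raise ParameterError(
            f"dimension mismatch: kernel {K.shape}, scores {vi.shape[0]}/{vj.shape[0]}"
        )
    keep_i = K.row_sums() >= support_threshold
    keep_j = K.col_sums() >= support_threshold
    if keep_i.sum() < 3 or keep_j.sum() < 3:
        raise InsufficientSupportError(
            "fewer than 3 cells with sufficient kernel support on one side"
        )
    W = K.weights[keep_i][:, keep_j]
    vi, vj = vi[keep_i], vj[keep_j]
    col = np.asarray(W.sum(axis=0)).ravel()
    row = np.asarray(W.sum(axis=1)).ravel()
    smoothed_j = np.asarray(W.T @ vi).ravel() / np.where(col > 0, col, 1.0)
    smoothed_i = np.asarray(W @ vj).ravel() / np.where(row > 0, row, 1.0)
    return 0.5 * (_pearson(smoothed_j, vj) + _pearson(vi, smoothed_i))


def select_bandwidth(
    samples,
    cell_types: list[str] | None = None,
    sigma_grid: list[float] | None = None,
    **fit_kwargs,
) -> tuple[float, pd.DataFrame]:
    """Choose the Gaussian-kernel bandwidth maximizing mean first-component NCorr.

    The first canonical component is fit (with an identical seed) at every
    bandwidth in the grid; the mean NCorr over all (type pair, sample) entries
    is the selection criterion, with ties broken toward the smaller bandwidth.
    Returns the selected bandwidth and the full profile table.
    """
    from .skrcca import _bandwidth_profile  # deferred: skrcca imports metrics

    if sigma_grid is None:
        sigma_grid = default_sigma_grid(samples)
    sigma_grid = [float(s) for s in sigma_grid]
    if not sigma_grid:
        raise ParameterError("sigma_grid must be nonempty")
    if any(s <= 0 for s in sigma_grid):
        raise ParameterError("bandwidths must be positive")
    profile = _bandwidth_profile(samples, cell_types, sigma_grid, **fit_kwargs)
    best = profile["mean_ncorr"].to_numpy()
    if np.all(~np.isfinite(best)):
        raise UndefinedMetricError("all bandwidth fits degenerate")
    order = np.argsort(profile["sigma"].to_numpy(), kind="stable")
    profile = profile.iloc[order].reset_index(drop=True)
    idx = int(np.nanargmax(profile["mean_ncorr"].to_numpy()))  # first max = smallest sigma
    return float(profile.loc[idx, "sigma"]), profile


def default_sigma_grid(samples, n: int = 8, lo: float = 0.01, hi: float = 0.30) -> list[float]:
    """Geometric grid spanning [lo, hi] of the coordinate-range diagonal."""
    if not isinstance(samples, (list, tuple)):
        samples = [samples]
    diags = []
    for s in samples:
        span = s.coords.max(axis=0) - s.coords.min(axis=0)
        diags.append(float(np.hypot(*span)))
    diag = float(np.median(diags))
    if diag <= 0:
        raise ParameterError("degenerate coordinates: zero spatial extent")
    return list(np.geomspace(lo * diag, hi * diag, n))
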