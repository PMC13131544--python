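"""Gene-space programs, cross-sample axis transfer, and kernel score propagation.

Because both the PCA embedding and the canonical objective are linear, a
PC-space weight vector corresponds to an exact gene-space linear functional
on standardized expression (back-projection).  An alternative regression
route — per-gene slope of standardized expression on the standardized score —
is less exact but more reproducible across replicates when PCs are unstable.
Gene programs can be transferred to another slide by standardizing the target
with reference statistics (optionally after per-gene quantile normalization)
and projecting; scores can also be propagated across cell types through a
cross-type kernel (kernel-weighted mean).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import DimensionError, ParameterError, ValidationError
from .io import TypeEmbedding
from .kernels import SpatialKernel
from . import metrics as _metrics

logger = logging.getLogger(__name__)

DEFAULT_MIN_OVERLAP = 0.5


@dataclass
class GeneProgram:
    """A canonical axis expressed as weights over the full gene space.

    ``gene_weights`` has shape (m, K); evaluating it on expression
    standardized by ``gene_mean``/``gene_sd`` reproduces the PC-space scores
    (exactly for the back-projection method).  ``reference_sorted`` holds the
    per-gene sorted reference values used for quantile mapping in transfer;
    it may be None, in which case quantile normalization is unavailable.
    """

    cell_type: str
    component: int
    gene_weights: np.ndarray  # (m, K)
    gene_names: list[str]
    gene_mean: np.ndarray
    gene_sd: np.ndarray
    method: str  # "backprojection" | "regression"
    reference_sorted: np.ndarray | None = None  # (n_ref, m)

    def __post_init__(self) -> None:
        self.gene_weights = np.atleast_2d(np.asarray(self.gene_weights, dtype=float))
        if self.gene_weights.shape[0] != len(self.gene_names):
            self.gene_weights = self.gene_weights.T
        if not np.all(np.isfinite(self.gene_weights)):
            raise ValidationError("gene weights must be finite")

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for k in range(self.gene_weights.shape[1]):
            for g, name in enumerate(self.gene_names):
                rows.append((name, self.gene_weights[g, k], self.cell_type, k + 1))
        return pd.DataFrame(rows, columns=["gene", "weight", "cell_type", "component"])


@dataclass
class TransferResult:
    """Projected scores on a target slide plus per-pair fidelity metrics."""

    projected_scores: dict[tuple[str, str], np.ndarray]
    fidelity: pd.DataFrame | None = None


def gene_weights_backproject(
    embedding: TypeEmbedding,
    W: np.ndarray,
    reference_expression: np.ndarray | None = None,
    component: int = 1,
) -> GeneProgram:
    """Project PC-space canonical weights back to an exact gene-space functional.

    For whitened scores ``X = Z* V diag(1/s)`` the functional is
    ``g = V diag(1/s) w``: evaluating g on standardized expression equals
    ``X w``.  Genes excluded for zero within-type variance get weight 0, so
    the vector always spans the full gene list.
    """
    W = np.atleast_2d(np.asarray(W, dtype=float))
    if W.shape[0] != embedding.n_components:
        W = W.T
    if W.shape[0] != embedding.n_components:
        raise DimensionError(
            f"weight rows {W.shape} do not match embedding dimension {embedding.n_components}"
        )
    g_kept = embedding.loadings @ (W / embedding.score_scale[:, None])
    m = len(embedding.gene_names)
    G = np.zeros((m, W.shape[1]))
    G[embedding.kept_genes] = g_kept
    return GeneProgram(
        cell_type=embedding.cell_type,
        component=component,
        gene_weights=G,
        gene_names=list(embedding.gene_names),
        gene_mean=embedding.gene_mean,
        gene_sd=embedding.gene_sd,
        method="backprojection",
        reference_sorted=np.sort(reference_expression, axis=0)
        if reference_expression is not None
        else None,
    )


def gene_weights_regression(
    Z: np.ndarray,
    scores: np.ndarray,
    gene_names: list[str],
    cell_type: str = "",
    component: int = 1,
    keep_reference: bool = True,
) -> GeneProgram:
    """Per-gene regression slope of standardized expression on the standardized score.

    With both sides standardized the slope equals cov(g, s)/var(s), i.e. the
    per-gene Pearson correlation with the progression score.
    """
    Z = np.asarray(Z, dtype=float)
    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    if scores.shape[0] == 1:
        scores = scores.T
    if scores.shape[0] != Z.shape[0]:
        raise DimensionError("scores length does not match expression rows")
    sd_s = scores.std(axis=0)
    if np.any(sd_s == 0):
        raise ParameterError("constant score vector: regression undefined")
    s_std = (scores - scores.mean(axis=0)) / sd_s
    gene_mean = Z.mean(axis=0)
    gene_sd = Z.std(axis=0)
    ok = gene_sd > 0
    Zc = np.zeros_like(Z)
    Zc[:, ok] = (Z[:, ok] - gene_mean[ok]) / gene_sd[ok]
    G = Zc.T @ s_std / Z.shape[0]  # cov of standardized pairs = slope
    sd_out = np.where(ok, gene_sd, 1.0)
    return GeneProgram(
        cell_type=cell_type,
        component=component,
        gene_weights=G,
        gene_names=list(gene_names),
        gene_mean=gene_mean,
        gene_sd=sd_out,
        method="regression",
        reference_sorted=np.sort(Z, axis=0) if keep_reference else None,
    )


def _quantile_map(target: np.ndarray, sorted_ref: np.ndarray) -> np.ndarray:
    """Rank-map target values onto the reference distribution.

    Midpoint ranks (ties averaged) are linearly interpolated into the sorted
    reference values.
    """
    n = target.shape[0]
    order = np.argsort(target, kind="stable")
    ranks = np.empty(n)
    ranks[order] = np.arange(1, n + 1)
    # average ranks over ties
    sorted_vals = target[order]
    _, first, counts = np.unique(sorted_vals, return_index=True, return_counts=True)
    avg = first + (counts + 1) / 2.0  # 1-based average rank within each tie group
    tie_rank = np.repeat(avg, counts)
    ranks[order] = tie_rank
    p = (ranks - 0.5) / n
    nref = sorted_ref.shape[0]
    grid = (np.arange(1, nref + 1) - 0.5) / nref
    return np.interp(p, grid, sorted_ref)


def transfer_scores(
    program: GeneProgram,
    target_Z: np.ndarray,
    target_gene_names: list[str] | None = None,
    quantile_normalize: bool = True,
    min_overlap: float = DEFAULT_MIN_OVERLAP,
) -> np.ndarray:
    """Project a gene program onto a target expression matrix.

    Target genes are mapped onto the reference gene order; genes missing from
    the target are imputed at the reference mean, which zeroes their
    standardized contribution (logged).  With ``quantile_normalize`` each
    target gene's values are rank-mapped onto the reference gene's sorted
    values before standardization by the reference mean/sd — this makes the
    projection invariant to monotone per-gene distortions of the target.
    """
    target_Z = np.asarray(target_Z, dtype=float)
    m = len(program.gene_names)
    W = program.gene_weights
    if target_gene_names is None:
        if target_Z.shape[1] != m:
            raise DimensionError("target has wrong gene count and no gene names given")
        target_gene_names = list(program.gene_names)
    col_of = {g: j for j, g in enumerate(target_gene_names)}
    n = target_Z.shape[0]
    X = np.tile(program.gene_mean, (n, 1))
    present = np.zeros(m, dtype=bool)
    for g_idx, g in enumerate(program.gene_names):
        j = col_of.get(g)
        if j is not None:
            X[:, g_idx] = target_Z[:, j]
            present[g_idx] = True
    informative = np.any(W != 0, axis=1)
    n_info = int(informative.sum())
    overlap = present[informative].mean() if n_info else 1.0
    if overlap < min_overlap:
        raise ValidationError(
            f"only {overlap:.0%} of nonzero-weight genes present in target "
            f"(threshold {min_overlap:.0%})"
        )
    n_missing = int((~present & informative).sum())
    if n_missing:
        logger.info("transfer: %d informative genes absent from target (weight dropped)", n_missing)
    if quantile_normalize:
        if program.reference_sorted is None:
            raise ParameterError(
                "quantile_normalize requires reference values stored in the program"
            )
        for g_idx in np.flatnonzero(present & informative):
            X[:, g_idx] = _quantile_map(X[:, g_idx], program.reference_sorted[:, g_idx])
    sd = np.where(program.gene_sd > 0, program.gene_sd, 1.0)
    X_std = (X - program.gene_mean) / sd
    out = X_std @ W
    return out[:, 0] if out.shape[1] == 1 else out


def kernel_propagate_scores(
    source_scores: np.ndarray,
    cross_kernel: SpatialKernel | np.ndarray,
    normalize: bool = True,
    support_threshold: float = _metrics.DEFAULT_SUPPORT_THRESHOLD,
) -> np.ndarray:
    """Propagate scores from one population to another through a cross kernel.

    Kernel rows index target cells and columns index source cells:
    ``target_j = sum_i K[j, i] v_i``, divided by the row sum when
    ``normalize`` (kernel-weighted mean).  Target cells whose kernel row sum
    falls below ``support_threshold`` are returned as NaN.
    """
    K = (
        cross_kernel
        if isinstance(cross_kernel, SpatialKernel)
        else SpatialKernel(np.asarray(cross_kernel, float), 1.0)
    )
    v = np.asarray(source_scores, dtype=float).ravel()
    if K.shape[1] != v.shape[0]:
        raise DimensionError(
            f"kernel source dimension {K.shape[1]} does not match scores {v.shape[0]}"
        )
    num = K.matvec(v)
    rows = K.row_sums()
    out = np.asarray(num, dtype=float)
    if normalize:
        with np.errstate(divide="ignore", invalid="ignore"):
            out = np.where(rows > 0, out / rows, np.nan)
    undefined = rows < support_threshold
    if undefined.any():
        logger.info("kernel propagation: %d target cells with negligible support", int(undefined.sum()))
        out = out.copy()
        out[undefined] = np.nan
    return out


def assess_transfer(
    transfer: TransferResult,
    kernels: dict,
    support_threshold: float = _metrics.DEFAULT_SUPPORT_THRESHOLD,
) -> pd.DataFrame:
    """NCorr/BSC fidelity of projected scores under target-slide kernels.

    ``kernels`` maps (sample_id, (type_i, type_j)) to target-slide kernels at
    the chosen bandwidth (within-type pairs give self-kernel BSC).  Returns a
    long table per pair and sample plus aggregate medians in the attrs.
    """
    rows = []
    for (q, (ta, tb)), K in kernels.items():
        vi = np.asarray(transfer.projected_scores[(q, ta)], dtype=float)
        vj = np.asarray(transfer.projected_scores[(q, tb)], dtype=float)
        try:
            nc = _metrics.ncorr(vi, vj, K)
        except Exception:  # degenerate scores: keep the row, flag NaN
            nc = np.nan
        try:
            bs = _metrics.bsc(vi, vj, K, support_threshold=support_threshold)
        except Exception:
            bs = np.nan
        rows.append({"sample_id": q, "type_i": ta, "type_j": tb, "ncorr": nc, "bsc": bs})
    df = pd.DataFrame(rows)
    df.attrs["median_ncorr"] = float(df["ncorr"].median()) if len(df) else np.nan
    df.attrs["median_bsc"] = float(df["bsc"].median()) if len(df) else np.nan
    transfer.fidelity = df
    return df


def quantile_summary(scores: np.ndarray, q: float = 0.9) -> float:
    """Per-sample score aggregation by quantile (e.g. a 90th-percentile summary)."""
    if not 0 <= q <= 1:
        raise ParameterError("q must lie in [0, 1]")
    return float(np.nanquantile(np.asarray(scores, dtype=float), q))
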