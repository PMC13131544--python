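"""Spatial-kernel-restricted CCA: solvers, deflation, and the fit pipeline.

The objective generalizes classical CCA by re-weighting the cross-cell-type
covariance with a spatial proximity kernel.  With T cell types, Q samples,
whitened per-type PC embeddings X_{t,q} and kernels K_{ij,q}(sigma), a single
component solves

    max_{w_1..w_T}  sum_q sum_{i<j}  w_i' X_{i,q}' K_{ij,q} X_{j,q} w_j
    s.t.  ||w_t|| = 1  for all t,

by block-coordinate power iteration (default) or a damped coordinate-descent
variant.  For a single cell type the objective is the quadratic form
w' X'KX w, whose optimum is the leading eigenvector of the symmetrized
matrix — no iteration.  Higher components come from sequential deflation of
the score direction out of each embedding.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.spatial.distance import cdist

from .exceptions import (
    DegenerateKernelError,
    DegenerateSupervisionError,
    DimensionError,
    ParameterError,
    UndefinedMetricError,
    ValidationError,
)
from .io import SpatialSample, TypeEmbedding, embed_type_multi
from .kernels import SpatialKernel, gaussian_kernel, morphology_filtered_distances
from . import metrics as _metrics

logger = logging.getLogger(__name__)

DEFAULT_MAX_ITER = 500
DEFAULT_TOL = 1e-6
DEFAULT_RESTARTS = 5
DEFAULT_ALPHA = 0.5


class ComponentFit(dict):
    """Mapping cell type -> unit weight vector, with convergence metadata."""

    objective: float = np.nan
    n_iter: int = 0
    delta: float = np.nan
    objective_path: list | None = None


@dataclass
class CoProgressionFit:
    """Result of a spatial-kernel-restricted CCA fit.

    ``weights[t]`` is the (d_t, K) canonical weight matrix for cell type t;
    ``cell_scores[(sample_id, t)]`` the (n_t, K) progression scores; ``metrics``
    a long table of NCorr/BSC per (component, type pair, sample).
    """

    weights: dict[str, np.ndarray]
    cell_scores: dict[tuple[str, str], np.ndarray]
    metrics: pd.DataFrame
    sigma: float
    n_components: int
    convergence: list[dict]
    cell_types: list[str]
    embeddings: dict[tuple[str, str], TypeEmbedding]
    bandwidth_profile: pd.DataFrame | None = None
    config: dict = field(default_factory=dict)

    def scores_for(self, cell_type: str, component: int = 1) -> np.ndarray:
        """Concatenated scores of one type across samples, in sample order."""
        cols = [
            v[:, component - 1]
            for (q, t), v in self.cell_scores.items()
            if t == cell_type
        ]
        return np.concatenate(cols)

    def mean_ncorr(self, component: int = 1) -> float:
        sub = self.metrics[self.metrics["component"] == component]
        return float(sub["ncorr"].mean())

    def save(self, out_dir: str | Path) -> Path:
        """Serialize as a directory of CSVs plus metrics.json and config.yaml."""
        from .programs import gene_weights_backproject  # deferred circular import

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        wrows = []
        for t, W in self.weights.items():
            for k in range(W.shape[1]):
                for p in range(W.shape[0]):
                    wrows.append((t, k + 1, p + 1, W[p, k]))
        pd.DataFrame(wrows, columns=["cell_type", "component", "pc_index", "value"]).to_csv(
            out / "weights.csv", index=False
        )
        grows = []
        for t, W in self.weights.items():
            emb = next(e for (q, tt), e in self.embeddings.items() if tt == t)
            prog = gene_weights_backproject(emb, W)
            for k in range(W.shape[1]):
                for g, name in enumerate(emb.gene_names):
                    grows.append((name, prog.gene_weights[g, k], t, k + 1))
        pd.DataFrame(grows, columns=["gene", "weight", "cell_type", "component"]).to_csv(
            out / "gene_weights.csv", index=False
        )
        srows = []
        for (q, t), S in self.cell_scores.items():
            ids = self.embeddings[(q, t)].cell_ids
            df = pd.DataFrame(S, columns=[f"CC_{k + 1}" for k in range(S.shape[1])])
            df.insert(0, "cell_type", t)
            df.insert(0, "sample_id", q)
            df.insert(0, "cell_id", ids)
            srows.append(df)
        pd.concat(srows, ignore_index=True).to_csv(out / "scores.csv", index=False)
        self.metrics.to_csv(out / "metrics.csv", index=False)
        meta = {
            "sigma": float(self.sigma),
            "n_components": int(self.n_components),
            "cell_types": list(self.cell_types),
            "convergence": self.convergence,
        }
        with open(out / "metrics.json", "w", encoding="utf-8") as fh:
            import json

            json.dump(meta, fh, indent=2, default=float)
        with open(out / "config.yaml", "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.config, fh)
        if self.bandwidth_profile is not None:
            self.bandwidth_profile.to_csv(out / "bandwidth_profile.csv", index=False)
        return out


# ---------------------------------------------------------------------------
# component solvers


def _cross_matrices(
    embeddings: dict[tuple[str, str], TypeEmbedding],
    kernels: dict,
    types: list[str],
) -> dict[tuple[str, str, str], np.ndarray]:
    """C[(q, ti, tj)] = X_i' K_ij X_j for every kernel entry, oriented ti < tj."""
    order = {t: i for i, t in enumerate(types)}
    C: dict[tuple[str, str, str], np.ndarray] = {}
    for key, K in kernels.items():
        q, (ta, tb) = key
        if ta not in order or tb not in order:
            continue
        if order[ta] > order[tb]:
            ta, tb = tb, ta
            K = K.transpose()
        Xi = embeddings[(q, ta)].scores
        Xj = embeddings[(q, tb)].scores
        if K.shape != (Xi.shape[0], Xj.shape[0]):
            raise DimensionError(
                f"kernel {key}: shape {K.shape} inconsistent with embeddings "
                f"({Xi.shape[0]}, {Xj.shape[0]})"
            )
        C[(q, ta, tb)] = Xi.T @ K.matmat(Xj)
    return C


def _block_update(
    C: dict, types: list[str], t: str, w: dict[str, np.ndarray]
) -> np.ndarray:
    """Gradient direction for type t: sum of kernel-weighted partner projections."""
    u = None
    for (q, ta, tb), M in C.items():
        if ta == t:
            v = M @ w[tb]
        elif tb == t:
            v = M.T @ w[ta]
        else:
            continue
        u = v if u is None else u + v
    if u is None:
        raise DegenerateKernelError(f"no kernel involves type {t!r}")
    return u


def _objective(C: dict, w: dict[str, np.ndarray]) -> float:
    return float(sum(w[ta] @ M @ w[tb] for (q, ta, tb), M in C.items()))


def fit_component(
    embeddings: dict[tuple[str, str], TypeEmbedding],
    kernels: dict,
    method: str = "power",
    alpha: float = DEFAULT_ALPHA,
    fixed_weights: dict[str, np.ndarray] | None = None,
    max_iter: int = DEFAULT_MAX_ITER,
    tol: float = DEFAULT_TOL,
    seed: int = 0,
    restarts: int = DEFAULT_RESTARTS,
    track_objective: bool = False,
) -> ComponentFit:
    """Estimate one set of unit-norm canonical weight vectors, one per cell type.

    ``embeddings`` maps (sample_id, cell_type) to a :class:`TypeEmbedding`;
    ``kernels`` maps (sample_id, (type_i, type_j)) to the cross-type kernel.
    Types listed in ``fixed_weights`` are held at the given unit vector and
    never updated (supervised mode).  The non-convex objective is attacked
    from ``restarts`` random initializations; the best objective wins.
    """
    if method not in ("power", "coordinate_descent"):
        raise ParameterError(f"unknown method {method!r}")
    if not 0 < alpha < 1:
        raise ParameterError("alpha must lie in (0, 1)")
    types: list[str] = []
    for (_q, t) in embeddings:
        if t not in types:
            types.append(t)
    dims = {t: embeddings[next(k for k in embeddings if k[1] == t)].scores.shape[1] for t in types}
    for (q, t), emb in embeddings.items():
        if emb.scores.shape[1] != dims[t]:
            raise DimensionError(f"embedding dims for type {t!r} differ across samples")
    fixed = {}
    for t, v in (fixed_weights or {}).items():
        v = np.asarray(v, dtype=float).ravel()
        if t not in dims:
            raise ParameterError(f"fixed weight for unknown type {t!r}")
        if v.shape[0] != dims[t]:
            raise DimensionError(f"fixed weight for {t!r} has length {v.shape[0]}, want {dims[t]}")
        nv = np.linalg.norm(v)
        if nv == 0:
            raise ParameterError(f"fixed weight for {t!r} has zero norm")
        fixed[t] = v / nv
    free = [t for t in types if t not in fixed]
    if not free:
        raise ParameterError("all cell types fixed: nothing to optimize")
    C = _cross_matrices(embeddings, kernels, types)
    rng = np.random.default_rng(seed)
    best: ComponentFit | None = None
    n_restarts = restarts if len(free) > 0 else 1
    # a single free type is a linear problem: one restart suffices
    if len(free) == 1:
        n_restarts = 1
    for _r in range(n_restarts):
        w = {t: fixed[t].copy() for t in fixed}
        for t in free:
            v = rng.standard_normal(dims[t])
            w[t] = v / np.linalg.norm(v)
        path = [] if track_objective else None
        n_iter, delta = 0, np.inf
        for n_iter in range(1, max_iter + 1):
            delta = 0.0
            for t in free:
                u = _block_update(C, types, t, w)
                nu = np.linalg.norm(u)
                if not np.isfinite(nu) or nu == 0:
                    pairs = [k[1:] for k in C if t in k[1:]]
                    raise DegenerateKernelError(
                        f"degenerate update for type {t!r} (pairs {pairs}): "
                        "kernel carries no weight in the embedding row space"
                    )
                if method == "power":
                    w_new = u / nu
                else:
                    mix = (1 - alpha) * w[t] + alpha * (u / nu)
                    nm = np.linalg.norm(mix)
                    if nm == 0:
                        raise DegenerateKernelError(f"vanishing damped update for {t!r}")
                    w_new = mix / nm
                delta = max(delta, float(np.linalg.norm(w_new - w[t])))
                w[t] = w_new
            if path is not None:
                path.append(_objective(C, w))
            if delta < tol:
                break
        obj = _objective(C, w)
        if best is None or obj > best.objective:
            best = ComponentFit(w)
            best.objective = obj
            best.n_iter = n_iter
            best.delta = delta
            best.objective_path = path
    return best


def fit_within(embedding: TypeEmbedding, kernel: SpatialKernel) -> np.ndarray:
    """Leading-eigenvector solution for a single cell type (no iteration).

    Maximizes ``w' X'KX w`` over unit vectors: the optimum is the leading
    eigenvector of the symmetrized matrix.  Near-ties are broken toward the
    eigenvector with the largest |first coordinate|, and the sign is oriented
    so the largest-magnitude entry is positive.
    """
    if kernel.shape[0] != kernel.shape[1]:
        raise DimensionError(f"within-type kernel must be square, got {kernel.shape}")
    X = embedding.scores
    if kernel.shape[0] != X.shape[0]:
        raise DimensionError("kernel size does not match embedding rows")
    M = X.T @ kernel.matmat(X)
    M = 0.5 * (M + M.T)
    return _leading_eigvec(M)


def _orient_vector(w: np.ndarray) -> np.ndarray:
    i = int(np.argmax(np.abs(w)))
    return -w if w[i] < 0 else w.copy()


def _leading_eigvec(M: np.ndarray) -> np.ndarray:
    """Leading eigenvector of a symmetric matrix with deterministic tie-breaks.

    Within a (near-)degenerate top eigenspace the basis returned by the
    eigensolver is arbitrary; the first-coordinate rule projects e1 onto that
    subspace, which reduces to e1 itself under full degeneracy.
    """
    evals, evecs = np.linalg.eigh(M)
    top = evals[-1]
    ties = np.flatnonzero(evals >= top - 1e-9 * max(abs(top), 1.0))
    cand = evecs[:, ties]
    proj = cand @ cand[0]  # projection of e1 onto the tied eigenspace
    norm = np.linalg.norm(proj)
    if norm > 1e-8:
        return _orient_vector(proj / norm)
    j = int(np.argmax(np.abs(cand[0])))
    return _orient_vector(cand[:, j])


def deflate(
    embeddings: dict[tuple[str, str], TypeEmbedding],
    weights: dict[str, np.ndarray],
) -> dict[tuple[str, str], TypeEmbedding]:
    """Project each type's score direction v = Xw out of its embedding.

    Returns new embeddings with ``X <- X - v (v'X) / (v'v)`` applied per
    (sample, type); subsequent components' scores are therefore orthogonal to
    v within each sample.  Kernels are untouched and reused across components.
    """
    out = {}
    for key, emb in embeddings.items():
        _q, t = key
        new = emb.copy()
        if t in weights:
            w = np.asarray(weights[t], dtype=float).ravel()
            if w.shape[0] != emb.scores.shape[1]:
                raise DimensionError(f"weight length mismatch for type {t!r}")
            v = emb.scores @ w
            vv = float(v @ v)
            if vv <= 1e-300:
                warnings.warn(
                    f"zero-norm score direction for {key}; deflation skipped",
                    stacklevel=2,
                )
            else:
                new.scores = emb.scores - np.outer(v, v @ emb.scores) / vv
        out[key] = new
    return out


def supervised_reference_weights(
    embedding: TypeEmbedding, ordinal_labels: np.ndarray
) -> np.ndarray:
    """Unit-norm OLS coefficients of ordinal labels regressed on PC scores.

    Encodes a known anatomical ordering (e.g. nephron segments along the
    corticomedullary axis) as a reference weight vector usable as a fixed
    first component in supervised fits.
    """
    y = np.asarray(ordinal_labels, dtype=float).ravel()
    X = embedding.scores
    if y.shape[0] != X.shape[0]:
        raise DimensionError("label length does not match cell count")
    if np.unique(y).size < 2:
        raise DegenerateSupervisionError("ordinal labels are constant")
    design = np.column_stack([np.ones_like(y), X])
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    w = coef[1:]
    nw = np.linalg.norm(w)
    if nw == 0:
        raise DegenerateSupervisionError("labels are orthogonal to all PC scores")
    return w / nw


# ---------------------------------------------------------------------------
# fit pipeline


class _Problem:
    """Embeddings, pairwise distances, and kernel construction for a fit."""

    def __init__(
        self,
        samples: list[SpatialSample],
        cell_types: list[str],
        n_pcs: int,
        scale: bool,
        whiten: bool,
        cutoff_quantile: float | None,
        kernel_variant: str,
        kernel_kwargs: dict | None,
    ):
        self.samples = samples
        self.cell_types = cell_types
        self.cutoff_quantile = cutoff_quantile
        self.within_mode = len(cell_types) == 1
        kernel_kwargs = dict(kernel_kwargs or {})
        self.embeddings: dict[tuple[str, str], TypeEmbedding] = {}
        for t in cell_types:
            per_sample = embed_type_multi(samples, t, n_components=n_pcs, scale=scale, whiten=whiten)
            for q, emb in per_sample.items():
                self.embeddings[(q, t)] = emb
        if self.within_mode:
            self.pairs = [(cell_types[0], cell_types[0])]
        else:
            self.pairs = [
                (cell_types[i], cell_types[j])
                for i in range(len(cell_types))
                for j in range(i + 1, len(cell_types))
            ]
        self.distances: dict[tuple[str, tuple[str, str]], np.ndarray] = {}
        for s in samples:
            filtered = None
            if kernel_variant == "morphology":
                filtered = morphology_filtered_distances(
                    s.coords,
                    k=int(kernel_kwargs.get("k", 10)),
                    reclassify_factor=float(kernel_kwargs.get("reclassify_factor", 2.0)),
                )
            for (ta, tb) in self.pairs:
                ra = self.embeddings[(s.sample_id, ta)].cell_rows
                rb = self.embeddings[(s.sample_id, tb)].cell_rows
                if filtered is not None:
                    d = filtered[np.ix_(ra, rb)]
                else:
                    d = cdist(s.coords[ra], s.coords[rb])
                self.distances[(s.sample_id, (ta, tb))] = d
        self._norm_cache: dict[tuple[float, str, tuple[str, str]], float] = {}

    def kernels_at(self, sigma: float) -> dict:
        out = {}
        for (q, pair), d in self.distances.items():
            out[(q, pair)] = gaussian_kernel(
                None,
                None,
                sigma,
                cutoff_quantile=self.cutoff_quantile,
                source_type=pair[0],
                target_type=pair[1],
                distances=d,
            )
        return out

    def spectral_norms(self, sigma: float, kernels: dict) -> dict:
        out = {}
        for key, K in kernels.items():
            cache_key = (float(sigma), key[0], key[1])
            if cache_key not in self._norm_cache:
                self._norm_cache[cache_key] = _metrics.spectral_norm(K)
            out[key] = self._norm_cache[cache_key]
        return out


def _as_sample_list(samples) -> list[SpatialSample]:
    if isinstance(samples, SpatialSample):
        return [samples]
    return list(samples)


def _component_scores(
    embeddings: dict, weights: dict[str, np.ndarray]
) -> dict[tuple[str, str], np.ndarray]:
    return {key: emb.scores @ weights[key[1]] for key, emb in embeddings.items()}


def _fit_within_multi(embeddings: dict, kernels: dict) -> np.ndarray:
    """Within-type mode across samples: leading eigenvector of the summed form."""
    M = None
    for (q, pair), K in kernels.items():
        X = embeddings[(q, pair[0])].scores
        Mq = X.T @ K.matmat(X)
        M = Mq if M is None else M + Mq
    M = 0.5 * (M + M.T)
    return _leading_eigvec(M)


def _bandwidth_profile(
    samples,
    cell_types: list[str] | None,
    sigma_grid: list[float],
    *,
    n_pcs: int = 40,
    scale: bool = True,
    whiten: bool = True,
    method: str = "power",
    alpha: float = DEFAULT_ALPHA,
    max_iter: int = DEFAULT_MAX_ITER,
    tol: float = DEFAULT_TOL,
    restarts: int = DEFAULT_RESTARTS,
    seed: int = 0,
    cutoff_quantile: float | None = None,
    kernel_variant: str = "gaussian",
    kernel_kwargs: dict | None = None,
    fixed_weights: dict | None = None,
    problem: "_Problem | None" = None,
) -> pd.DataFrame:
    """Mean first-component NCorr at every bandwidth in the grid (same seed)."""
    samples = _as_sample_list(samples)
    if cell_types is None:
        cell_types = sorted(set(samples[0].cell_type.tolist()))
    if problem is None:
        problem = _Problem(
            samples, cell_types, n_pcs, scale, whiten, cutoff_quantile, kernel_variant, kernel_kwargs
        )
    rows = []
    for sigma in sigma_grid:
        kernels = problem.kernels_at(sigma)
        norms = problem.spectral_norms(sigma, kernels)
        try:
            if problem.within_mode:
                w = _fit_within_multi(problem.embeddings, kernels)
                weights = {cell_types[0]: w}
            else:
                weights = fit_component(
                    problem.embeddings,
                    kernels,
                    method=method,
                    alpha=alpha,
                    fixed_weights=fixed_weights,
                    max_iter=max_iter,
                    tol=tol,
                    seed=seed,
                    restarts=restarts,
                )
        except DegenerateKernelError:
            rows.append({"sigma": sigma, "mean_ncorr": np.nan})
            continue
        row = {"sigma": sigma}
        vals = []
        for (q, (ta, tb)), K in kernels.items():
            vi = problem.embeddings[(q, ta)].scores @ weights[ta]
            vj = problem.embeddings[(q, tb)].scores @ weights[tb]
            try:
                nc = _metrics.ncorr(vi, vj, K, kernel_norm=norms[(q, (ta, tb))])
            except UndefinedMetricError:
                nc = np.nan
            row[f"{q}:{ta}|{tb}"] = nc
            vals.append(nc)
        row["mean_ncorr"] = float(np.nanmean(vals)) if vals else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def fit(
    samples,
    cell_types: list[str] | None = None,
    n_components: int = 1,
    sigma: float | None = None,
    *,
    sigma_grid: list[float] | None = None,
    n_pcs: int = 40,
    scale: bool = True,
    whiten: bool = True,
    method: str = "power",
    alpha: float = DEFAULT_ALPHA,
    max_iter: int = DEFAULT_MAX_ITER,
    tol: float = DEFAULT_TOL,
    restarts: int = DEFAULT_RESTARTS,
    seed: int = 0,
    cutoff_quantile: float | None = None,
    kernel_variant: str = "gaussian",
    kernel_kwargs: dict | None = None,
    fixed_weights: dict[str, np.ndarray] | None = None,
    support_threshold: float = _metrics.DEFAULT_SUPPORT_THRESHOLD,
    compute_bsc: bool = True,
) -> CoProgressionFit:
    """Run the full skrCCA pipeline on one or more spatial samples.

    Builds per-type whitened embeddings (with a pooled basis across samples),
    constructs Gaussian (or morphology-filtered) kernels, optionally selects
    the bandwidth by maximizing mean first-component NCorr over ``sigma_grid``,
    and extracts ``n_components`` canonical axes by repeated component fits
    and deflation.  A single cell type switches to within-type eigen mode.

    Each component's joint sign is oriented so the first cell type's scores
    correlate positively with that type's first principal component.
    """
    samples = _as_sample_list(samples)
    if not samples:
        raise ValidationError("no samples given")
    if n_components < 1:
        raise ParameterError("n_components must be >= 1")
    if cell_types is None:
        cell_types = sorted(set(samples[0].cell_type.tolist()))
    config = {
        "cell_types": list(cell_types),
        "n_components": n_components,
        "sigma": sigma,
        "sigma_grid": list(map(float, sigma_grid)) if sigma_grid is not None else None,
        "n_pcs": n_pcs,
        "scale": scale,
        "whiten": whiten,
        "method": method,
        "alpha": alpha,
        "max_iter": max_iter,
        "tol": tol,
        "restarts": restarts,
        "seed": seed,
        "cutoff_quantile": cutoff_quantile,
        "kernel_variant": kernel_variant,
        "support_threshold": support_threshold,
    }
    problem = _Problem(
        samples, cell_types, n_pcs, scale, whiten, cutoff_quantile, kernel_variant, kernel_kwargs
    )
    profile = None
    if sigma is None:
        if sigma_grid is None:
            sigma_grid = _metrics.default_sigma_grid(samples)
        profile = _bandwidth_profile(
            samples,
            cell_types,
            sigma_grid,
            n_pcs=n_pcs,
            scale=scale,
            whiten=whiten,
            method=method,
            alpha=alpha,
            max_iter=max_iter,
            tol=tol,
            restarts=restarts,
            seed=seed,
            fixed_weights=fixed_weights,
            problem=problem,
        )
        prof = profile.sort_values("sigma", kind="stable").reset_index(drop=True)
        if prof["mean_ncorr"].isna().all():
            raise UndefinedMetricError("all bandwidth fits degenerate")
        sigma = float(prof.loc[int(np.nanargmax(prof["mean_ncorr"].to_numpy())), "sigma"])
    config["sigma"] = float(sigma)
    kernels = problem.kernels_at(sigma)
    norms = problem.spectral_norms(sigma, kernels)

    all_fixed = fixed_weights is not None and all(t in fixed_weights for t in cell_types)
    cur = {k: v.copy() for k, v in problem.embeddings.items()}
    weights_out = {t: [] for t in cell_types}
    scores_out: dict[tuple[str, str], list] = {
        (s.sample_id, t): [] for s in samples for t in cell_types
    }
    metric_rows = []
    convergence = []
    first_type = cell_types[0]
    pc1_ref = np.concatenate(
        [problem.embeddings[(s.sample_id, first_type)].scores[:, 0] for s in samples]
    )
    for k in range(1, n_components + 1):
        comp_fixed = fixed_weights if k == 1 else None
        if problem.within_mode:
            w_vec = _fit_within_multi(cur, kernels)
            comp = ComponentFit({first_type: w_vec})
            comp.objective = float(
                sum(
                    w_vec @ (cur[(q, ta)].scores.T @ K.matmat(cur[(q, tb)].scores)) @ w_vec
                    for (q, (ta, tb)), K in kernels.items()
                )
            )
            comp.n_iter, comp.delta = 0, 0.0
        elif all_fixed and k == 1:
            comp = ComponentFit(
                {t: np.asarray(fixed_weights[t], float) / np.linalg.norm(fixed_weights[t]) for t in cell_types}
            )
            comp.objective = np.nan
            comp.n_iter, comp.delta = 0, 0.0
        else:
            comp = fit_component(
                cur,
                kernels,
                method=method,
                alpha=alpha,
                fixed_weights=comp_fixed,
                max_iter=max_iter,
                tol=tol,
                seed=seed + 7919 * (k - 1),
                restarts=restarts,
            )
        scores_k = _component_scores(cur, comp)
        # joint sign orientation: first type's scores vs its original PC1
        v1 = np.concatenate([scores_k[(s.sample_id, first_type)] for s in samples])
        orient = float(v1 @ pc1_ref)
        flip = orient < 0 and not (comp_fixed and first_type in (comp_fixed or {}))
        if flip:
            comp = ComponentFit({t: -w for t, w in comp.items()})
            scores_k = {key: -v for key, v in scores_k.items()}
        for t in cell_types:
            weights_out[t].append(comp[t])
        for key, v in scores_k.items():
            scores_out[key].append(v)
        for (q, (ta, tb)), K in kernels.items():
            vi = scores_k[(q, ta)]
            vj = scores_k[(q, tb)]
            try:
                nc = _metrics.ncorr(vi, vj, K, kernel_norm=norms[(q, (ta, tb))])
            except UndefinedMetricError:
                nc = np.nan
            bs = np.nan
            if compute_bsc:
                try:
                    bs = _metrics.bsc(vi, vj, K, support_threshold=support_threshold)
                except UndefinedMetricError:
                    bs = np.nan
            metric_rows.append(
                {
                    "component": k,
                    "type_i": ta,
                    "type_j": tb,
                    "sample_id": q,
                    "ncorr": nc,
                    "bsc": bs,
                }
            )
        convergence.append(
            {
                "component": k,
                "iterations": int(comp.n_iter),
                "delta": float(comp.delta),
                "objective": float(comp.objective),
            }
        )
        if k < n_components:
            cur = deflate(cur, comp)
    return CoProgressionFit(
        weights={t: np.column_stack(ws) for t, ws in weights_out.items()},
        cell_scores={key: np.column_stack(vs) for key, vs in scores_out.items()},
        metrics=pd.DataFrame(metric_rows),
        sigma=float(sigma),
        n_components=n_components,
        convergence=convergence,
        cell_types=list(cell_types),
        embeddings=problem.embeddings,
        bandwidth_profile=profile,
        config=config,
    )
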