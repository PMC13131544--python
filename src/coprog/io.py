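"""Loading, validation, and per-cell-type whitened PCA embeddings.

A spatial sample couples a cell-by-gene expression matrix with 2-D spatial
coordinates and a broad cell-type label per cell.  Within each cell type,
expression is centered (and optionally unit-variance scaled) and reduced by
PCA; the retained principal-component scores are whitened so that downstream
unit-norm canonical weights correspond to unit-variance progression scores.
"""

from __future__ import annotations

import csv
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
from sklearn.utils.extmath import randomized_svd

from .exceptions import (
    EmptySampleError,
    FormatError,
    InsufficientDataError,
    ValidationError,
)

logger = logging.getLogger(__name__)

DEFAULT_N_COMPONENTS = 40


@dataclass
class SpatialSample:
    """One slide: expression, coordinates, and cell-type labels, row-aligned."""

    sample_id: str
    expression: np.ndarray  # (n_cells, n_genes), nonnegative
    coords: np.ndarray  # (n_cells, 2)
    cell_type: np.ndarray  # (n_cells,) str
    gene_names: list[str]
    cell_ids: np.ndarray | None = None  # (n_cells,) str

    def __post_init__(self) -> None:
        self.expression = np.asarray(self.expression, dtype=float)
        self.coords = np.asarray(self.coords, dtype=float)
        self.cell_type = np.asarray(self.cell_type, dtype=object)
        n = self.expression.shape[0]
        if not (self.coords.shape[0] == n and self.cell_type.shape[0] == n):
            raise ValidationError(
                f"row mismatch: expression {n}, coords {self.coords.shape[0]}, "
                f"labels {self.cell_type.shape[0]}"
            )
        if self.coords.ndim != 2 or self.coords.shape[1] != 2:
            raise ValidationError("coords must be an (n_cells, 2) matrix")
        if not np.all(np.isfinite(self.coords)):
            raise ValidationError("coordinates must be finite")
        if len(self.gene_names) != self.expression.shape[1]:
            raise ValidationError("gene_names length must match expression columns")
        if len(set(self.gene_names)) != len(self.gene_names):
            raise ValidationError("duplicated gene names")
        if self.cell_ids is None:
            self.cell_ids = np.array(
                [f"cell_{i:06d}" for i in range(n)], dtype=object
            )
        else:
            self.cell_ids = np.asarray(self.cell_ids, dtype=object)
            if self.cell_ids.shape[0] != n:
                raise ValidationError("cell_ids length must match cell count")

    @property
    def n_cells(self) -> int:
        return self.expression.shape[0]

    @property
    def n_genes(self) -> int:
        return self.expression.shape[1]

    @property
    def cell_types(self) -> list[str]:
        return sorted(set(self.cell_type.tolist()))

    def subset(self, mask: np.ndarray) -> "SpatialSample":
        return SpatialSample(
            sample_id=self.sample_id,
            expression=self.expression[mask],
            coords=self.coords[mask],
            cell_type=self.cell_type[mask],
            gene_names=list(self.gene_names),
            cell_ids=self.cell_ids[mask],
        )

    def type_mask(self, cell_type: str) -> np.ndarray:
        return np.asarray(self.cell_type == cell_type)


@dataclass
class TypeEmbedding:
    """Whitened PC scores of one cell type, plus the decoder back to gene space.

    ``scores`` holds the per-cell PC scores (whitened by default).  ``loadings``
    has one orthonormal column per component over the *kept* genes (those with
    nonzero within-type variance); ``kept_genes`` maps back to the full gene
    space.  ``score_scale`` stores the raw PC-score standard deviations so the
    gene-space linear functional equivalent to a PC-space weight vector can be
    reconstructed exactly.
    """

    cell_type: str
    sample_id: str
    scores: np.ndarray  # (nt, dt)
    loadings: np.ndarray  # (m_kept, dt), orthonormal columns
    gene_mean: np.ndarray  # (m,) full gene space
    gene_sd: np.ndarray  # (m,) full gene space (1.0 where not scaled)
    n_components: int
    gene_names: list[str]
    kept_genes: np.ndarray  # (m,) bool
    score_scale: np.ndarray  # (dt,) sd of raw PC scores (1.0 if not whitened)
    scaled: bool
    whitened: bool
    cell_rows: np.ndarray | None = None  # row indices into the sample
    cell_ids: np.ndarray | None = None
    sample_rows: dict | None = None  # sample_id -> row slice, for pooled fits

    @property
    def n_cells(self) -> int:
        return self.scores.shape[0]

    def copy(self) -> "TypeEmbedding":
        out = TypeEmbedding(
            cell_type=self.cell_type,
            sample_id=self.sample_id,
            scores=self.scores.copy(),
            loadings=self.loadings,
            gene_mean=self.gene_mean,
            gene_sd=self.gene_sd,
            n_components=self.n_components,
            gene_names=self.gene_names,
            kept_genes=self.kept_genes,
            score_scale=self.score_scale,
            scaled=self.scaled,
            whitened=self.whitened,
            cell_rows=self.cell_rows,
            cell_ids=self.cell_ids,
            sample_rows=self.sample_rows,
        )
        return out


def _sniff_read_table(path: Path, **kwargs) -> pd.DataFrame:
    """Read a CSV/TSV table, sniffing the delimiter from the first line."""
    try:
        with open(path, "r", encoding="utf-8") as fh:
            first = fh.readline()
        delim = "\t" if first.count("\t") >= first.count(",") and "\t" in first else ","
        return pd.read_csv(path, sep=delim, **kwargs)
    except (OSError, pd.errors.ParserError, UnicodeDecodeError) as exc:
        raise FormatError(f"could not read table {path}: {exc}") from exc


def _read_expression(expr_path: Path) -> tuple[pd.Index, list[str], np.ndarray]:
    """Read expression as MTX triplet (with sidecars) or dense delimited table.

    Returns (cell index, gene names, dense cells-by-genes matrix).
    """
    if expr_path.suffix == ".mtx" or expr_path.name.endswith(".mtx.gz"):
        try:
            mat = scipy.io.mmread(str(expr_path))
        except (OSError, ValueError) as exc:
            raise FormatError(f"could not read MTX file {expr_path}: {exc}") from exc
        d = expr_path.parent
        feat = _find_sidecar(d, ("features.tsv", "genes.tsv", "features.csv"))
        barc = _find_sidecar(d, ("barcodes.tsv", "barcodes.csv"))
        genes = [
            r[0]
            for r in csv.reader(open(feat, encoding="utf-8"), delimiter="\t")
            if r
        ]
        cells = [
            r[0]
            for r in csv.reader(open(barc, encoding="utf-8"), delimiter="\t")
            if r
        ]
        mat = np.asarray(sp.csr_matrix(mat).todense())
        # CellRanger convention: genes x cells
        if mat.shape == (len(genes), len(cells)):
            mat = mat.T
        elif mat.shape != (len(cells), len(genes)):
            raise FormatError(
                f"MTX shape {mat.shape} matches neither (genes, cells)="
                f"({len(genes)}, {len(cells)}) nor its transpose"
            )
        return pd.Index(cells), genes, mat
    df = _sniff_read_table(expr_path, index_col=0)
    return df.index.astype(str), [str(g) for g in df.columns], df.to_numpy(dtype=float)


def _find_sidecar(d: Path, names: tuple[str, ...]) -> Path:
    for name in names:
        p = d / name
        if p.exists():
            return p
    raise FormatError(f"no sidecar file ({'/'.join(names)}) next to MTX in {d}")


def load_sample(
    expr_path: str | Path,
    coords_path: str | Path,
    meta_path: str | Path,
    sample_id: str | None = None,
) -> SpatialSample:
    """Load a spatial sample from an expression matrix plus coordinate/label tables.

    ``expr_path`` is either an MTX triplet member (``matrix.mtx`` with
    ``features.tsv``/``barcodes.tsv`` sidecars) or a dense CSV/TSV whose header
    row holds gene names and whose first column holds cell identifiers.
    ``coords_path`` needs columns ``cell_id,x,y``; ``meta_path`` needs
    ``cell_id,cell_type`` (optionally ``sample_id``).  The three tables are
    joined on the cell identifier; cells missing coordinates or a type label
    are dropped (count logged).
    """
    expr_path, coords_path, meta_path = Path(expr_path), Path(coords_path), Path(meta_path)
    cells, genes, mat = _read_expression(expr_path)
    if cells.duplicated().any():
        raise ValidationError(f"duplicate cell identifiers in {expr_path}")
    coords = _sniff_read_table(coords_path)
    meta = _sniff_read_table(meta_path)
    for name, df, cols in (
        ("coords", coords, {"cell_id", "x", "y"}),
        ("meta", meta, {"cell_id", "cell_type"}),
    ):
        missing = cols - set(df.columns)
        if missing:
            raise FormatError(f"{name} table missing columns {sorted(missing)}")
        if df["cell_id"].duplicated().any():
            raise ValidationError(f"duplicate cell identifiers in {name} table")
    coords = coords.set_index(coords["cell_id"].astype(str))
    meta = meta.set_index(meta["cell_id"].astype(str))
    keep = cells.intersection(coords.index).intersection(meta.index)
    keep = pd.Index([c for c in cells if c in set(keep)])  # preserve expression order
    n_dropped = len(cells) - len(keep)
    if n_dropped:
        logger.info(
            "dropped %d/%d cells missing coordinates or type labels", n_dropped, len(cells)
        )
    if len(keep) == 0:
        raise EmptySampleError("no cells with both coordinates and type labels")
    row_of = {c: i for i, c in enumerate(cells)}
    rows = np.array([row_of[c] for c in keep])
    if sample_id is None:
        if "sample_id" in meta.columns:
            sample_id = str(meta.loc[keep[0], "sample_id"])
        else:
            sample_id = expr_path.stem
    return SpatialSample(
        sample_id=sample_id,
        expression=mat[rows],
        coords=coords.loc[keep, ["x", "y"]].to_numpy(dtype=float),
        cell_type=meta.loc[keep, "cell_type"].astype(str).to_numpy(dtype=object),
        gene_names=genes,
        cell_ids=keep.to_numpy(dtype=object),
    )


def write_sample(sample: SpatialSample, out_dir: str | Path) -> Path:
    """Write a sample as an MTX triplet plus coordinate and metadata CSVs."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    mat = sp.coo_matrix(sample.expression.T)  # genes x cells, CellRanger convention
    scipy.io.mmwrite(str(out / "matrix.mtx"), mat)
    with open(out / "features.tsv", "w", encoding="utf-8") as fh:
        fh.write("\n".join(sample.gene_names) + "\n")
    with open(out / "barcodes.tsv", "w", encoding="utf-8") as fh:
        fh.write("\n".join(map(str, sample.cell_ids)) + "\n")
    pd.DataFrame(
        {"cell_id": sample.cell_ids, "x": sample.coords[:, 0], "y": sample.coords[:, 1]}
    ).to_csv(out / "coords.csv", index=False)
    pd.DataFrame(
        {
            "cell_id": sample.cell_ids,
            "cell_type": sample.cell_type,
            "sample_id": sample.sample_id,
        }
    ).to_csv(out / "meta.csv", index=False)
    return out


def _oriented_svd(Zc: np.ndarray, d: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Top-d SVD with a deterministic sign convention.

    Each component is oriented so the gene with the largest |loading| carries
    a positive loading, making weights reproducible and transferable.
    """
    n, m = Zc.shape
    if min(n, m) <= 600:
        U, S, Vt = np.linalg.svd(Zc, full_matrices=False)
        U, S, Vt = U[:, :d], S[:d], Vt[:d]
    else:
        U, S, Vt = randomized_svd(Zc, n_components=d, random_state=0, n_iter=7)
    for j in range(d):
        g = int(np.argmax(np.abs(Vt[j])))
        if Vt[j, g] < 0:
            Vt[j] = -Vt[j]
            U[:, j] = -U[:, j]
    return U, S, Vt


def embed_type(
    sample: SpatialSample,
    cell_type: str,
    n_components: int = DEFAULT_N_COMPONENTS,
    scale: bool = True,
    whiten: bool = True,
) -> TypeEmbedding:
    """Center/scale one cell type's expression and reduce it by (whitened) PCA.

    Genes with zero within-type variance are excluded before scaling and are
    re-inserted with zero loadings when decoding back to the full gene space.
    ``n_components`` is clipped (with a warning) to the available rank.
    """
    mask = sample.type_mask(cell_type)
    rows = np.flatnonzero(mask)
    Z = sample.expression[rows]
    nt = Z.shape[0]
    if nt < 3:
        raise InsufficientDataError(
            f"cell type {cell_type!r} has only {nt} cells; need at least 3"
        )
    m = Z.shape[1]
    gene_mean = Z.mean(axis=0)
    gene_var = Z.var(axis=0)
    kept = gene_var > 0
    if not kept.any():
        raise InsufficientDataError(f"all genes constant within type {cell_type!r}")
    gene_sd = np.ones(m)
    if scale:
        gene_sd[kept] = np.sqrt(gene_var[kept])
    Zc = (Z[:, kept] - gene_mean[kept]) / gene_sd[kept]
    max_d = min(nt - 1, int(kept.sum()))
    d = min(n_components, max_d)
    if d < n_components:
        warnings.warn(
            f"n_components={n_components} exceeds rank bound {max_d} for type "
            f"{cell_type!r}; clipped to {d}",
            stacklevel=2,
        )
    U, S, Vt = _oriented_svd(Zc, d)
    # drop numerically-zero singular values (cannot be whitened)
    nz = S > S[0] * 1e-12 if S.size and S[0] > 0 else np.zeros(S.shape, bool)
    if not nz.all():
        U, S, Vt = U[:, nz], S[nz], Vt[nz]
        d = int(nz.sum())
        warnings.warn(
            f"rank deficiency in type {cell_type!r}: kept {d} components",
            stacklevel=2,
        )
    if d == 0:
        raise InsufficientDataError(f"type {cell_type!r} has no expression variance")
    scores_raw = U * S
    score_scale = np.ones(d)
    if whiten:
        score_scale = S / np.sqrt(nt)  # column sd (columns have zero mean)
        scores = scores_raw / score_scale
    else:
        scores = scores_raw
    return TypeEmbedding(
        cell_type=cell_type,
        sample_id=sample.sample_id,
        scores=scores,
        loadings=Vt.T,
        gene_mean=gene_mean,
        gene_sd=gene_sd,
        n_components=d,
        gene_names=list(sample.gene_names),
        kept_genes=kept,
        score_scale=score_scale,
        scaled=scale,
        whitened=whiten,
        cell_rows=rows,
        cell_ids=sample.cell_ids[rows],
    )


def embed_type_multi(
    samples: list[SpatialSample],
    cell_type: str,
    n_components: int = DEFAULT_N_COMPONENTS,
    scale: bool = True,
    whiten: bool = True,
) -> dict[str, TypeEmbedding]:
    """Per-sample embeddings of one cell type on a common (pooled) PC basis.

    Cells of the type are pooled across samples, embedded once, and the score
    rows are split back per sample.  A shared basis is what makes a single set
    of canonical weights meaningful across slides.
    """
    if len({s.sample_id for s in samples}) != len(samples):
        raise ValidationError("duplicate sample_id among samples")
    if len(samples) == 1:
        return {samples[0].sample_id: embed_type(samples[0], cell_type, n_components, scale, whiten)}
    g0 = samples[0].gene_names
    for s in samples[1:]:
        if s.gene_names != g0:
            raise ValidationError("samples must share an identical gene list")
    parts, ids, offsets = [], [], [0]
    for s in samples:
        rows = np.flatnonzero(s.type_mask(cell_type))
        parts.append((s, rows))
        offsets.append(offsets[-1] + len(rows))
    pooled = SpatialSample(
        sample_id="__pooled__",
        expression=np.vstack([s.expression[r] for s, r in parts]),
        coords=np.vstack([s.coords[r] for s, r in parts]),
        cell_type=np.concatenate([s.cell_type[r] for s, r in parts]),
        gene_names=list(g0),
        cell_ids=np.concatenate(
            [np.char.add(s.sample_id + ":", s.cell_ids[r].astype(str)) for s, r in parts]
        ),
    )
    base = embed_type(pooled, cell_type, n_components, scale, whiten)
    out: dict[str, TypeEmbedding] = {}
    for i, (s, rows) in enumerate(parts):
        sl = slice(offsets[i], offsets[i + 1])
        emb = base.copy()
        emb.sample_id = s.sample_id
        emb.scores = base.scores[sl]
        emb.cell_rows = rows
        emb.cell_ids = s.cell_ids[rows]
        out[s.sample_id] = emb
    return out
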