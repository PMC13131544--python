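"""Shared fixtures: small deterministic samples and embeddings."""

import numpy as np
import pytest

from coprog.io import SpatialSample, TypeEmbedding, embed_type
from coprog import simulate as sim


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def make_sample(
    n_per_type=40, n_genes=15, types=("A", "B"), seed=0, sample_id="s0"
) -> SpatialSample:
    """Small two-type sample: smooth latent field + noise, uniform coordinates."""
    rng = np.random.default_rng(seed)
    n = n_per_type * len(types)
    coords = rng.uniform(0, 1, size=(n, 2))
    field = np.sin(2 * np.pi * coords[:, 0]) + coords[:, 1]
    load = rng.standard_normal(n_genes)
    expr = np.outer(field, load) + 0.5 * rng.standard_normal((n, n_genes))
    expr = np.logaddexp(0, expr)
    cell_type = np.repeat(list(types), n_per_type).astype(object)
    return SpatialSample(
        sample_id=sample_id,
        expression=expr,
        coords=coords,
        cell_type=cell_type,
        gene_names=[f"g{i}" for i in range(n_genes)],
    )


@pytest.fixture
def toy_sample():
    return make_sample()


@pytest.fixture
def toy_embedding(toy_sample):
    return embed_type(toy_sample, "A", n_components=5)


def make_embedding(X, cell_type="A", sample_id="q"):
    """Wrap a raw (already whitened) score matrix as a TypeEmbedding."""
    X = np.asarray(X, dtype=float)
    n, d = X.shape
    return TypeEmbedding(
        cell_type=cell_type,
        sample_id=sample_id,
        scores=X,
        loadings=np.eye(d),
        gene_mean=np.zeros(d),
        gene_sd=np.ones(d),
        n_components=d,
        gene_names=[f"g{i}" for i in range(d)],
        kept_genes=np.ones(d, dtype=bool),
        score_scale=np.ones(d),
        scaled=True,
        whitened=True,
        cell_rows=np.arange(n),
        cell_ids=np.array([f"c{i}" for i in range(n)], dtype=object),
    )


def whiten_view(X):
    """Center a view and whiten it so X'X = n I (classical-CCA preprocessing)."""
    X = X - X.mean(axis=0)
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    return U * np.sqrt(X.shape[0])


@pytest.fixture(scope="session")
def alt2_small():
    """One small coordinated-gradient simulation shared across tests."""
    return sim.simulate_scenario("alt2", n_cells=600, seed=1)
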