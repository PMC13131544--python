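"""Solvers for the kernel-restricted CCA objective, deflation, supervision."""

import numpy as np
import pytest

from coprog.exceptions import (
    DegenerateSupervisionError,
    DimensionError,
    ParameterError,
)
from coprog.io import embed_type
from coprog.kernels import SpatialKernel, gaussian_kernel
from coprog.metrics import ncorr
from coprog.skrcca import (
    deflate,
    fit,
    fit_component,
    fit_within,
    supervised_reference_weights,
)

from conftest import make_embedding, make_sample, whiten_view


def _cca_instance(seed, n=80, d=6, shared=3):
    """Two matched whitened views with shared latent structure + CCA oracle."""
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n, shared))
    X1 = whiten_view(z @ rng.standard_normal((shared, d)) + 0.5 * rng.standard_normal((n, d)))
    X2 = whiten_view(z @ rng.standard_normal((shared, d)) + 0.5 * rng.standard_normal((n, d)))
    U, S, Vt = np.linalg.svd(X1.T @ X2)
    embs = {("q", "t1"): make_embedding(X1, "t1"), ("q", "t2"): make_embedding(X2, "t2")}
    kern = {("q", ("t1", "t2")): SpatialKernel(np.eye(n), 1.0, "t1", "t2")}
    return embs, kern, U[:, 0], Vt[0], S[0], n


class TestFitComponent:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_identity_kernel_reproduces_classical_cca(self, seed):
        embs, kern, u1, v1, s1, n = _cca_instance(seed)
        comp = fit_component(embs, kern, seed=seed, tol=1e-12, max_iter=5000)
        # objective equals first canonical correlation times n
        np.testing.assert_allclose(comp.objective, s1, rtol=1e-9)
        assert abs(abs(comp["t1"] @ u1) - 1) < 1e-6
        assert abs(abs(comp["t2"] @ v1) - 1) < 1e-6

    def test_fixed_type_one_step_conditional_optimum(self):
        embs, kern, u1, v1, s1, n = _cca_instance(5)
        comp = fit_component(embs, kern, fixed_weights={"t1": u1}, seed=0)
        # conditional optimum is a single matrix-vector product
        M = embs[("q", "t1")].scores.T @ embs[("q", "t2")].scores
        expected = M.T @ u1
        expected /= np.linalg.norm(expected)
        np.testing.assert_allclose(np.abs(comp["t2"] @ expected), 1.0, atol=1e-9)
        np.testing.assert_allclose(comp["t1"], u1, atol=1e-12)

    def test_objective_nondecreasing_over_power_iterations(self):
        embs, kern, *_ = _cca_instance(7)
        comp = fit_component(embs, kern, seed=3, restarts=1, track_objective=True)
        path = np.asarray(comp.objective_path)
        assert np.all(np.diff(path) >= -1e-9)

    def test_all_fixed_rejected(self):
        embs, kern, u1, v1, *_ = _cca_instance(1)
        with pytest.raises(ParameterError, match="nothing to optimize"):
            fit_component(embs, kern, fixed_weights={"t1": u1, "t2": v1})

    def test_permutation_invariance(self):
        """Relabeling cells (kernel permuted consistently) leaves the fit unchanged."""
        embs, kern, *_ = _cca_instance(11)
        comp = fit_component(embs, kern, seed=4, tol=1e-10)
        rng = np.random.default_rng(0)
        n = embs[("q", "t1")].scores.shape[0]
        perm = rng.permutation(n)
        embs2 = {k: v.copy() for k, v in embs.items()}
        embs2[("q", "t1")].scores = embs[("q", "t1")].scores[perm]
        K = kern[("q", ("t1", "t2"))].dense()[perm, :]
        kern2 = {("q", ("t1", "t2")): SpatialKernel(K, 1.0, "t1", "t2")}
        comp2 = fit_component(embs2, kern2, seed=4, tol=1e-10)
        np.testing.assert_allclose(comp2.objective, comp.objective, rtol=1e-8)
        np.testing.assert_allclose(np.abs(comp2["t1"] @ comp["t1"]), 1.0, atol=1e-6)

    def test_multi_sample_copies_match_single(self):
        embs, kern, *_ = _cca_instance(13)
        embs3 = {}
        kern3 = {}
        for q in ("a", "b", "c"):
            for (_, t), e in embs.items():
                e2 = e.copy()
                e2.sample_id = q
                embs3[(q, t)] = e2
            kern3[(q, ("t1", "t2"))] = kern[("q", ("t1", "t2"))]
        c1 = fit_component(embs, kern, seed=2, tol=1e-10)
        c3 = fit_component(embs3, kern3, seed=2, tol=1e-10)
        np.testing.assert_allclose(np.abs(c1["t1"] @ c3["t1"]), 1.0, atol=1e-7)
        np.testing.assert_allclose(np.abs(c1["t2"] @ c3["t2"]), 1.0, atol=1e-7)

    def test_invalid_alpha_and_method(self):
        embs, kern, *_ = _cca_instance(0)
        with pytest.raises(ParameterError):
            fit_component(embs, kern, method="nope")
        with pytest.raises(ParameterError):
            fit_component(embs, kern, method="coordinate_descent", alpha=1.5)

    def test_coordinate_descent_reaches_power_solution(self):
        embs, kern, u1, *_ = _cca_instance(3)
        comp = fit_component(
            embs, kern, method="coordinate_descent", alpha=0.5, seed=1, tol=1e-10, max_iter=3000
        )
        assert abs(abs(comp["t1"] @ u1) - 1) < 1e-5


class TestFitWithin:
    def test_identity_kernel_tie_broken_by_first_coordinate(self):
        X = whiten_view(np.random.default_rng(0).standard_normal((40, 4)))
        emb = make_embedding(X)
        w = fit_within(emb, SpatialKernel(np.eye(40), 1.0))
        # X'X = n I: every unit vector ties; first-coordinate rule selects e1
        np.testing.assert_allclose(np.abs(w[0]), 1.0, atol=1e-6)

    def test_dominant_block_concentrates_on_pc1(self):
        rng = np.random.default_rng(1)
        n = 60
        X = whiten_view(rng.standard_normal((n, 5)))
        # kernel aligned with PC1 structure: weight cells by PC1 outer product
        v = X[:, 0]
        K = np.outer(v, v)
        K = np.exp(K / np.abs(K).max())  # positive weights, PC1-dominant
        w = fit_within(emb := make_embedding(X), SpatialKernel(K, 1.0))
        # dense eigensolver oracle
        M = X.T @ K @ X
        evals, evecs = np.linalg.eigh(0.5 * (M + M.T))
        np.testing.assert_allclose(np.abs(w @ evecs[:, -1]), 1.0, atol=1e-8)
        assert abs(w[0]) > 0.9

    def test_beats_random_search(self):
        rng = np.random.default_rng(2)
        X = whiten_view(rng.standard_normal((50, 6)))
        K = gaussian_kernel(rng.uniform(size=(50, 2)), rng.uniform(size=(50, 2)), 0.3)
        K = SpatialKernel(0.5 * (K.dense() + K.dense().T), 0.3)
        emb = make_embedding(X)
        w = fit_within(emb, K)
        M = X.T @ K.dense() @ X
        best_random = max(
            (v := r / np.linalg.norm(r)) @ M @ v
            for r in rng.standard_normal((1000, 6))
        )
        assert w @ M @ w >= best_random - 1e-9

    def test_non_square_kernel_rejected(self):
        emb = make_embedding(np.eye(4))
        with pytest.raises(DimensionError):
            fit_within(emb, SpatialKernel(np.ones((4, 3)), 1.0))


class TestDeflate:
    def test_idempotent_projection_zeroes_scores(self):
        embs, kern, *_ = _cca_instance(4)
        comp = fit_component(embs, kern, seed=0)
        defl = deflate(embs, comp)
        for key, emb in defl.items():
            v = emb.scores @ comp[key[1]]
            np.testing.assert_allclose(v, 0.0, atol=1e-8)

    def test_frobenius_norm_strictly_contracts(self):
        embs, kern, *_ = _cca_instance(6)
        comp = fit_component(embs, kern, seed=0)
        defl = deflate(embs, comp)
        for key in embs:
            assert np.linalg.norm(defl[key].scores) < np.linalg.norm(embs[key].scores)

    def test_component_scores_orthogonal_within_sample(self, alt2_small):
        sample, truth = alt2_small
        result = fit(sample, n_components=3, sigma=0.1, seed=0)
        for key, S in result.cell_scores.items():
            for a in range(3):
                for b in range(a + 1, 3):
                    ip = abs(S[:, a] @ S[:, b])
                    assert ip < 1e-6 * np.linalg.norm(S[:, a]) * np.linalg.norm(S[:, b])

    def test_weight_columns_unit_norm(self, alt2_small):
        sample, _ = alt2_small
        result = fit(sample, n_components=2, sigma=0.1, seed=0)
        for W in result.weights.values():
            np.testing.assert_allclose(np.linalg.norm(W, axis=0), 1.0, atol=1e-8)


class TestSupervised:
    def test_labels_equal_pc1_recover_e1(self, toy_embedding):
        w = supervised_reference_weights(toy_embedding, toy_embedding.scores[:, 0])
        expected = np.zeros(toy_embedding.n_components)
        expected[0] = 1
        np.testing.assert_allclose(np.abs(w), expected, atol=1e-8)

    def test_known_combination_closed_form(self, toy_embedding):
        """labels = 2*PC1 + PC2 on whitened scores -> weight (2,1,0,..)/sqrt(5)."""
        y = 2 * toy_embedding.scores[:, 0] + toy_embedding.scores[:, 1]
        w = supervised_reference_weights(toy_embedding, y)
        expected = np.zeros(toy_embedding.n_components)
        expected[:2] = [2, 1]
        expected /= np.sqrt(5)
        np.testing.assert_allclose(w, expected, atol=1e-8)

    def test_constant_labels_rejected(self, toy_embedding):
        with pytest.raises(DegenerateSupervisionError):
            supervised_reference_weights(toy_embedding, np.ones(toy_embedding.n_cells))

    def test_all_fixed_fit_is_noop_evaluation(self, alt2_small):
        """With every type's weights fixed, fit evaluates NCorr without moving them."""
        sample, _ = alt2_small
        base = fit(sample, n_components=1, sigma=0.1, seed=0)
        fixed = {t: base.weights[t][:, 0] for t in base.cell_types}
        ev = fit(sample, n_components=1, sigma=0.1, seed=1, fixed_weights=fixed)
        for t in base.cell_types:
            np.testing.assert_allclose(ev.weights[t][:, 0], fixed[t], atol=1e-12)
        # NCorr matches a direct formula computation
        row = ev.metrics.iloc[0]
        embA = ev.embeddings[(sample.sample_id, row["type_i"])]
        embB = ev.embeddings[(sample.sample_id, row["type_j"])]
        K = gaussian_kernel(
            sample.coords[embA.cell_rows], sample.coords[embB.cell_rows], 0.1
        )
        direct = ncorr(
            embA.scores @ fixed[row["type_i"]], embB.scores @ fixed[row["type_j"]], K
        )
        np.testing.assert_allclose(row["ncorr"], direct, atol=1e-9)


class TestFitPipeline:
    def test_k1_two_types_matches_fit_component(self):
        sample = make_sample(n_per_type=50, n_genes=12, seed=9)
        result = fit(sample, n_components=1, sigma=0.15, n_pcs=5, seed=3)
        from coprog.skrcca import _Problem

        prob = _Problem([sample], ["A", "B"], 5, True, True, None, "gaussian", None)
        comp = fit_component(prob.embeddings, prob.kernels_at(0.15), seed=3)
        for t in ("A", "B"):
            np.testing.assert_allclose(
                np.abs(result.weights[t][:, 0] @ comp[t]), 1.0, atol=1e-8
            )

    def test_fit_recovers_planted_gradient(self, alt2_small):
        from coprog import simulate as sim

        sample, truth = alt2_small
        result = fit(sample, sigma=0.1, seed=0)
        assert sim.recovery_correlation(result, truth, sample) > 0.9

    def test_second_component_recovers_second_program(self):
        """Two orthogonal planted axes: deflation exposes the second one."""
        from coprog import simulate as sim

        sample, truth = sim.simulate_scenario("ortho2", n_cells=800, seed=3)
        result = fit(sample, n_components=2, sigma=0.1, seed=0)
        R = np.array(
            [
                [sim.recovery_correlation(result, truth, sample, component=k, axis=a) for a in (1, 2)]
                for k in (1, 2)
            ]
        )
        a1 = int(np.argmax(R[0]))
        assert R[0, a1] > 0.9
        assert R[1, 1 - a1] > 0.9

    def test_within_type_single_population_mode(self):
        sample = make_sample(n_per_type=60, n_genes=10, types=("A",), seed=5)
        result = fit(sample, cell_types=["A"], n_components=2, sigma=0.2, n_pcs=4, seed=0)
        assert result.weights["A"].shape == (4, 2)
        assert np.isfinite(result.metrics["ncorr"]).all()

    def test_fit_save_roundtrip(self, tmp_path, alt2_small):
        sample, _ = alt2_small
        result = fit(sample, n_components=1, sigma=0.1, seed=0)
        out = result.save(tmp_path / "fit")
        for name in ("weights.csv", "gene_weights.csv", "scores.csv", "metrics.json", "config.yaml"):
            assert (out / name).exists()
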