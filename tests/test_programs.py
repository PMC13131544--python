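"""Gene programs, cross-sample transfer, kernel score propagation."""

import numpy as np
import pytest

from coprog.exceptions import DimensionError, ParameterError, ValidationError
from coprog.io import embed_type
from coprog.kernels import SpatialKernel, gaussian_kernel
from coprog.programs import (
    TransferResult,
    assess_transfer,
    gene_weights_backproject,
    gene_weights_regression,
    kernel_propagate_scores,
    quantile_summary,
    transfer_scores,
)

from conftest import make_sample


@pytest.fixture
def embedding_and_Z():
    sample = make_sample(n_per_type=50, n_genes=12, seed=8)
    emb = embed_type(sample, "A", n_components=5)
    Z = sample.expression[emb.cell_rows]
    return emb, Z


class TestBackprojection:
    def test_basis_vector_gives_pc1_loadings(self, embedding_and_Z):
        emb, Z = embedding_and_Z
        e1 = np.zeros(emb.n_components)
        e1[0] = 1
        prog = gene_weights_backproject(emb, e1)
        expected = np.zeros(len(emb.gene_names))
        expected[emb.kept_genes] = emb.loadings[:, 0] / emb.score_scale[0]
        np.testing.assert_allclose(prog.gene_weights[:, 0], expected, atol=1e-12)

    def test_gene_space_evaluation_reproduces_scores(self, embedding_and_Z):
        """The back-projected functional on standardized expression equals X w."""
        emb, Z = embedding_and_Z
        rng = np.random.default_rng(0)
        w = rng.standard_normal(emb.n_components)
        w /= np.linalg.norm(w)
        prog = gene_weights_backproject(emb, w)
        Zs = (Z - prog.gene_mean) / np.where(prog.gene_sd > 0, prog.gene_sd, 1.0)
        got = Zs @ prog.gene_weights[:, 0]
        want = emb.scores @ w
        assert np.linalg.norm(got - want) <= 1e-6 * np.linalg.norm(want)

    def test_orthogonal_weight_columns_give_orthogonal_scores(self, embedding_and_Z):
        emb, Z = embedding_and_Z
        W = np.zeros((emb.n_components, 2))
        W[0, 0] = W[1, 1] = 1
        prog = gene_weights_backproject(emb, W)
        Zs = (Z - prog.gene_mean) / np.where(prog.gene_sd > 0, prog.gene_sd, 1.0)
        S = Zs @ prog.gene_weights
        assert abs(S[:, 0] @ S[:, 1]) < 1e-6 * np.linalg.norm(S[:, 0]) * np.linalg.norm(S[:, 1])

    def test_dimension_mismatch_rejected(self, embedding_and_Z):
        emb, _ = embedding_and_Z
        with pytest.raises(DimensionError):
            gene_weights_backproject(emb, np.ones(emb.n_components + 3))


class TestRegressionWeights:
    def test_gene_equal_to_score_has_slope_one(self, rng):
        s = rng.standard_normal(200)
        Z = np.column_stack([s, rng.standard_normal(200)])
        prog = gene_weights_regression(Z, s, ["g0", "g1"])
        assert prog.gene_weights[0, 0] == pytest.approx(1.0)

    def test_independent_gene_small_slope(self):
        rng = np.random.default_rng(11)
        s = rng.standard_normal(1000)
        Z = rng.standard_normal((1000, 3))
        prog = gene_weights_regression(Z, s, ["a", "b", "c"])
        assert np.all(np.abs(prog.gene_weights) < 0.1)

    def test_matches_covariance_formula_bruteforce(self, rng):
        Z = rng.standard_normal((60, 5)) * rng.uniform(1, 3, size=5)
        s = rng.standard_normal(60)
        prog = gene_weights_regression(Z, s, [f"g{i}" for i in range(5)])
        s_std = (s - s.mean()) / s.std()
        for g in range(5):
            z = (Z[:, g] - Z[:, g].mean()) / Z[:, g].std()
            slope = np.cov(z, s_std, bias=True)[0, 1] / np.var(s_std)
            assert prog.gene_weights[g, 0] == pytest.approx(slope, abs=1e-10)

    def test_constant_score_rejected(self, rng):
        with pytest.raises(ParameterError):
            gene_weights_regression(rng.standard_normal((10, 2)), np.ones(10), ["a", "b"])


class TestTransferScores:
    def _program(self, seed=0, n=80, m=10):
        rng = np.random.default_rng(seed)
        Z = np.abs(rng.standard_normal((n, m))) + 0.1
        s = Z @ rng.standard_normal(m)
        prog = gene_weights_regression(Z, s, [f"g{i}" for i in range(m)])
        return prog, Z, s

    @pytest.mark.parametrize("qn", [True, False])
    def test_self_transfer_reproduces_scores(self, qn):
        prog, Z, _ = self._program()
        got = transfer_scores(prog, Z, quantile_normalize=qn)
        Zs = (Z - prog.gene_mean) / prog.gene_sd
        want = Zs @ prog.gene_weights[:, 0]
        assert np.linalg.norm(got - want) <= 1e-6 * max(np.linalg.norm(want), 1.0)

    def test_doubled_gene_restored_by_rank_mapping(self):
        prog, Z, _ = self._program(seed=1)
        target = Z.copy()
        target[:, 2] *= 2.0
        got = transfer_scores(prog, target, quantile_normalize=True)
        base = transfer_scores(prog, Z, quantile_normalize=True)
        np.testing.assert_allclose(got, base, atol=1e-9)

    def test_monotone_distortion_better_with_quantile_norm(self):
        prog, Z, _ = self._program(seed=2)
        ref_scores = transfer_scores(prog, Z, quantile_normalize=False)
        distorted = np.exp(Z / Z.max())  # monotone per-gene distortion
        with_qn = transfer_scores(prog, distorted, quantile_normalize=True)
        without = transfer_scores(prog, distorted, quantile_normalize=False)
        r_with = np.corrcoef(with_qn, ref_scores)[0, 1]
        r_without = np.corrcoef(without, ref_scores)[0, 1]
        assert r_with > r_without

    def test_gene_column_order_invariance(self):
        prog, Z, _ = self._program(seed=3)
        rng = np.random.default_rng(0)
        perm = rng.permutation(Z.shape[1])
        names = [prog.gene_names[j] for j in perm]
        got = transfer_scores(prog, Z[:, perm], target_gene_names=names)
        base = transfer_scores(prog, Z)
        np.testing.assert_allclose(got, base, atol=1e-9)

    def test_low_overlap_rejected(self):
        prog, Z, _ = self._program(seed=4)
        with pytest.raises(ValidationError, match="nonzero-weight genes"):
            transfer_scores(prog, Z[:, :3], target_gene_names=prog.gene_names[:3])

    def test_missing_gene_imputed_at_reference_mean(self):
        prog, Z, _ = self._program(seed=5)
        keep = list(range(1, Z.shape[1]))  # drop gene 0
        got = transfer_scores(
            prog, Z[:, keep], target_gene_names=[prog.gene_names[j] for j in keep],
            quantile_normalize=False,
        )
        Zs = (Z - prog.gene_mean) / prog.gene_sd
        Zs[:, 0] = 0.0
        want = Zs @ prog.gene_weights[:, 0]
        np.testing.assert_allclose(got, want, atol=1e-9)


class TestKernelPropagation:
    def test_one_hot_row_copies_source_score(self):
        K = np.zeros((2, 3))
        K[0, 1] = 1.0
        K[1, 2] = 1.0
        v = np.array([5.0, 7.0, -2.0])
        out = kernel_propagate_scores(v, K, normalize=True)
        np.testing.assert_allclose(out, [7.0, -2.0])

    def test_constant_scores_propagate_unchanged(self, rng):
        K = rng.uniform(0.2, 1.0, size=(6, 8))
        out = kernel_propagate_scores(np.full(8, 3.5), K, normalize=True)
        np.testing.assert_allclose(out, 3.5)

    def test_uniform_kernel_gives_mean(self, rng):
        v = rng.standard_normal(10)
        K = np.ones((4, 10))
        np.testing.assert_allclose(
            kernel_propagate_scores(v, K, normalize=True), v.mean()
        )

    def test_rescaling_invariance_when_normalized(self, rng):
        K = rng.uniform(0.1, 1.0, size=(5, 7))
        v = rng.standard_normal(7)
        a = kernel_propagate_scores(v, K, normalize=True)
        b = kernel_propagate_scores(v, 3.7 * K, normalize=True)
        np.testing.assert_allclose(a, b, atol=1e-12)

    def test_unsupported_targets_flagged_nan(self):
        K = np.ones((3, 4))
        K[1, :] = 1e-6
        out = kernel_propagate_scores(np.ones(4), K, normalize=True)
        assert np.isnan(out[1])
        assert np.isfinite(out[[0, 2]]).all()


class TestAssessTransfer:
    def test_self_transfer_fidelity_matches_fit_metrics(self, alt2_small):
        from coprog.skrcca import fit

        sample, _ = alt2_small
        result = fit(sample, sigma=0.1, seed=0)
        scores = {
            (sample.sample_id, t): result.cell_scores[(sample.sample_id, t)][:, 0]
            for t in result.cell_types
        }
        kernels = {}
        ta, tb = result.cell_types
        ea = result.embeddings[(sample.sample_id, ta)]
        eb = result.embeddings[(sample.sample_id, tb)]
        kernels[(sample.sample_id, (ta, tb))] = gaussian_kernel(
            sample.coords[ea.cell_rows], sample.coords[eb.cell_rows], 0.1,
            source_type=ta, target_type=tb,
        )
        fid = assess_transfer(TransferResult(scores), kernels)
        np.testing.assert_allclose(
            fid["ncorr"].to_numpy(), result.metrics["ncorr"].to_numpy(), atol=1e-6
        )
        np.testing.assert_allclose(
            fid["bsc"].to_numpy(), result.metrics["bsc"].to_numpy(), atol=1e-6
        )

    def test_replicate_sample_transfer_preserves_bsc(self):
        """Transfer to a second sample from the same generator keeps BSC close."""
        from coprog import simulate as sim
        from coprog.skrcca import fit

        gaps = []
        for seed in (1, 2, 3):
            pool = sim.synth_expression_pool(1000, seed=seed)
            src, _ = sim.simulate_scenario(
                "alt2", n_cells=500, seed=seed, pool=pool, program_seed=7
            )
            tgt, _ = sim.simulate_scenario(
                "alt2", n_cells=500, seed=seed + 100, pool=pool, program_seed=7
            )
            result = fit(src, sigma=0.1, seed=0)
            proj = {}
            for t in result.cell_types:
                emb = result.embeddings[(src.sample_id, t)]
                prog = gene_weights_regression(
                    src.expression[emb.cell_rows],
                    result.cell_scores[(src.sample_id, t)][:, 0],
                    src.gene_names,
                    cell_type=t,
                )
                proj[(tgt.sample_id, t)] = transfer_scores(prog, tgt.expression[tgt.type_mask(t)])
            ta, tb = result.cell_types
            K = gaussian_kernel(
                tgt.coords[tgt.type_mask(ta)], tgt.coords[tgt.type_mask(tb)], 0.1
            )
            fid = assess_transfer(TransferResult(proj), {(tgt.sample_id, (ta, tb)): K})
            src_bsc = result.metrics["bsc"].iloc[0]
            gaps.append(abs(fid["bsc"].iloc[0] - src_bsc))
        assert np.mean(gaps) < 0.15


def test_quantile_summary():
    x = np.arange(101, dtype=float)
    assert quantile_summary(x, 0.9) == pytest.approx(90.0)
    with pytest.raises(ParameterError):
        quantile_summary(x, 1.5)
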