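import numpy as np
import pytest

from conftest import manual_dataset
from multiblup import gblup, gls_si, snp_blup
from multiblup.datamodel import VarianceComponents
from multiblup.gblup import SingularCovarianceError


class TestBuildGram:
    def test_identity_coding_gives_identity(self):
        ds, _ = manual_dataset(Z=np.eye(2), W=np.zeros((2, 2)), y=[0.0, 0.0])
        G = gblup.build_gram(ds, "additive")
        np.testing.assert_array_equal(G.values, np.eye(2))

    def test_matches_stacked_product_oracle(self, tiny2):
        ds, _, _ = tiny2
        S = np.vstack(ds.Z_list())
        G = gblup.build_gram(ds, "additive")
        np.testing.assert_allclose(G.values, S @ S.T, rtol=1e-12)
        Sw = np.vstack(ds.W_list())
        Gd = gblup.build_gram(ds, "dominance")
        np.testing.assert_allclose(Gd.values, Sw @ Sw.T, rtol=1e-12)

    def test_clone_rows_identical(self, clones):
        ds, _, _ = clones
        G = gblup.build_gram(ds, "additive").values
        # fixture clones record 0 into the last record of population 1
        last = ds.populations[0].n - 1
        np.testing.assert_allclose(G[0], G[last], rtol=1e-12)


class TestBuildScaledCov:
    def test_zero_cross_covariance_zeroes_off_diagonal_blocks(self, tiny2):
        ds, _, _ = tiny2
        vc = VarianceComponents(np.eye(2) * 0.1, np.eye(2) * 0.04, [1, 1])
        M = gblup.build_scaled_cov(ds, vc, "additive")
        s1, s2 = M.block_slices
        assert np.all(M.values[s1, s2] == 0)

    def test_single_snp_scalar_algebra(self):
        ds, vc = manual_dataset(Z=[[1.0], [-1.0]], W=[[0.0], [0.0]],
                                y=[0.0, 0.0], sigma_a2=2.0)
        M = gblup.build_scaled_cov(ds, vc, "additive")
        np.testing.assert_allclose(M.values, [[2, -2], [-2, 2]], rtol=1e-12)

    def test_matches_blockwise_oracle(self, equiv3):
        ds, vc, _ = equiv3
        M = gblup.build_scaled_cov(ds, vc, "additive").values
        Z = ds.Z_list()
        for i in (0, 2):
            for j in (1, 2):
                si, sj = ds.record_slices()[i], ds.record_slices()[j]
                np.testing.assert_allclose(
                    M[si, sj], vc.g0a[i, j] * Z[i] @ Z[j].T, rtol=1e-12
                )


class TestBlend:
    def test_zero_matrix_uses_unit_scale(self):
        np.testing.assert_allclose(
            gblup.blend(np.zeros((2, 2)), 0.01), 0.01 * np.eye(2)
        )

    def test_identity(self):
        np.testing.assert_allclose(gblup.blend(np.eye(3), 0.01), 1.01 * np.eye(3))

    def test_negative_epsilon_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            gblup.blend(np.eye(2), -0.1)

    def test_restores_rank_on_clones(self, clones):
        ds, vc, _ = clones
        GA = gblup.build_scaled_cov(ds, vc, "additive").values
        with pytest.raises(SingularCovarianceError):
            gblup._robust_inverse(GA, "G_A", 0.0)
        gblup._robust_inverse(GA, "G_A", 1e-6)  # blended: must succeed
        np.linalg.cholesky(gblup.blend(GA, 1e-6))

    def test_eigenvalue_floor(self):
        rng = np.random.default_rng(2)
        A = rng.standard_normal((6, 3))
        M = A @ A.T  # PSD, rank 3
        eps = 1e-4
        s = np.mean(np.diag(M))
        w = np.linalg.eigvalsh(gblup.blend(M, eps))
        assert w.min() >= eps * s * (1 - 1e-10)


class TestStandardSystem:
    def test_random_equation_count(self, equiv3):
        ds, vc, _ = equiv3
        system = gblup.build_standard_system(ds, vc)
        assert system.layout["random_equations"] == 2 * ds.P * ds.n

    def test_kronecker_block_pattern(self, equiv3):
        # LHS additive block (trait k, pop-block i; trait l, pop-block j)
        # must equal G*^{(ij)} g0a^{kl} off the data diagonal
        ds, vc, _ = equiv3
        system = gblup.build_standard_system(ds, vc)
        GA_inv = np.linalg.inv(gblup.build_gram(ds, "additive").values)
        g = vc.g0a_inv
        n, a0 = ds.n, system.layout["a0"]
        rng = np.random.default_rng(0)
        for _ in range(8):
            k, l = rng.integers(0, ds.P, size=2)
            if k == l:
                l = (k + 1) % ds.P  # off-diagonal trait pair: no data part
            sl_k = slice(a0 + k * n, a0 + (k + 1) * n)
            sl_l = slice(a0 + l * n, a0 + (l + 1) * n)
            np.testing.assert_allclose(
                system.lhs[sl_k, sl_l], GA_inv * g[k, l], rtol=1e-12, atol=1e-12
            )

    def test_singular_gram_without_blending_advises_blend(self, clones):
        ds, vc, _ = clones
        with pytest.raises(SingularCovarianceError, match="blend"):
            gblup.build_standard_system(ds, vc)

    def test_matches_snp_blup_on_full_rank_fixture(self, equiv3):
        ds, vc, _ = equiv3
        sol = gblup.solve(gblup.build_standard_system(ds, vc))
        ref = snp_blup.solve(snp_blup.build_system(ds, vc))
        np.testing.assert_allclose(sol.beta, ref.beta, rtol=1e-6)
        np.testing.assert_allclose(sol.u_a, ref.u_a, rtol=1e-6, atol=1e-9)
        np.testing.assert_allclose(sol.u_d, ref.u_d, rtol=1e-6, atol=1e-9)


class TestCompactSystem:
    def test_random_equation_count(self, equiv3):
        ds, vc, _ = equiv3
        system = gblup.build_compact_system(ds, vc)
        assert system.layout["random_equations"] == 2 * ds.n

    def test_zero_phenotypes_give_zero_solutions(self, equiv3):
        import copy

        ds, vc, _ = equiv3
        ds0 = copy.deepcopy(ds)
        for pop in ds0.populations:
            pop.y[:] = 0.0
        sol = gblup.solve(gblup.build_compact_system(ds0, vc))
        assert np.max(np.abs(sol.u_a)) < 1e-12

    def test_matches_snp_blup(self, equiv3):
        ds, vc, _ = equiv3
        sol = gblup.solve(gblup.build_compact_system(ds, vc))
        ref = snp_blup.solve(snp_blup.build_system(ds, vc))
        np.testing.assert_allclose(sol.beta, ref.beta, rtol=1e-6)
        np.testing.assert_allclose(sol.u_a, ref.u_a, rtol=1e-6, atol=1e-9)
        np.testing.assert_allclose(sol.u_d, ref.u_d, rtol=1e-6, atol=1e-9)

    def test_singularity_contrast_with_gls(self, clones):
        # compact GBLUP needs blending on clones; GLS+SI runs unblended
        # because V = G_A + G_D + R is invertible by construction
        ds, vc, _ = clones
        with pytest.raises(SingularCovarianceError):
            gblup.build_compact_system(ds, vc)
        gblup.solve(gblup.build_compact_system(ds, vc, blend_epsilon=1e-6))
        sol = gls_si.solve(ds, vc)
        ref = snp_blup.solve(snp_blup.build_system(ds, vc))
        np.testing.assert_allclose(sol.a_hat, ref.a_hat, rtol=1e-6, atol=1e-12)


class TestBacksolveMarkers:
    def test_zero_genetic_values_give_zero_effects(self, tiny2):
        import copy

        ds, vc, _ = tiny2
        ds0 = copy.deepcopy(ds)
        for pop in ds0.populations:
            pop.y[:] = 0.0
        system = gblup.build_compact_system(ds0, vc)
        sol = gblup.solve(system)
        a_hat, d_hat = gblup.backsolve_markers(system, sol)
        assert np.max(np.abs(a_hat)) < 1e-12

    def test_matches_snp_blup(self, equiv3):
        ds, vc, _ = equiv3
        system = gblup.build_compact_system(ds, vc)
        sol = gblup.solve(system)
        a_hat, d_hat = gblup.backsolve_markers(system, sol)
        ref = snp_blup.solve(snp_blup.build_system(ds, vc))
        np.testing.assert_allclose(a_hat, ref.a_hat, rtol=1e-6, atol=1e-10)
        np.testing.assert_allclose(d_hat, ref.d_hat, rtol=1e-6, atol=1e-10)

    def test_two_record_closed_form(self):
        # single population, two records, full-rank codings so the compact
        # covariances are invertible without blending; backsolved effects
        # must match the selection-index closed form
        # a_hat = sigma_a2 Z' V^{-1} (y - X bhat)
        Z = np.array([[1.0, 0.0], [-1.0, 1.0]])
        W = np.array([[1.0, 0.0], [0.0, 1.0]])
        y = np.array([1.0, -1.0])
        ds, vc = manual_dataset(Z=Z, W=W, y=y, sigma_a2=2.0, sigma_d2=0.5)
        system = gblup.build_compact_system(ds, vc)
        sol = gblup.solve(system)
        a_hat, d_hat = gblup.backsolve_markers(system, sol)
        V = 2.0 * Z @ Z.T + 0.5 * W @ W.T + np.eye(2)
        X = np.ones((2, 1))
        Vi = np.linalg.inv(V)
        bhat = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ y)
        resid = Vi @ (y - X @ bhat)
        np.testing.assert_allclose(a_hat[0], 2.0 * Z.T @ resid, rtol=1e-10)
        np.testing.assert_allclose(d_hat[0], 0.5 * W.T @ resid, rtol=1e-10)

    def test_blended_system_refused(self, clones):
        ds, vc, _ = clones
        system = gblup.build_compact_system(ds, vc, blend_epsilon=1e-6)
        sol = gblup.solve(system)
        with pytest.raises(ValueError, match="blend"):
            gblup.backsolve_markers(system, sol)

    def test_standard_formulation_refused(self, equiv3):
        ds, vc, _ = equiv3
        system = gblup.build_standard_system(ds, vc)
        sol = gblup.solve(system)
        with pytest.raises(ValueError, match="compact"):
            gblup.backsolve_markers(system, sol)
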