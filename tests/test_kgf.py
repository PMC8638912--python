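"""Kernel graph filter components against hand values and brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from hypothesis.extra.numpy import arrays

import kgfpet as kp
from kgfpet.kgf import (
    KGFConfig,
    adaptive_k,
    apply_graph_filter,
    center_kernel,
    kernel_matrix,
    kernel_pca_scores,
    knn_adjacency,
    linear_kernel_matrix,
    markov_transition,
    normalize_frames,
    optimal_order,
)

from conftest import growing_sinogram_set


class TestNormalizeFrames:
    def test_l1_hand_value(self):
        np.testing.assert_allclose(
            normalize_frames(np.array([[2.0], [2.0]]), "l1"), [[0.5], [0.5]]
        )

    def test_none_is_identity(self, rng):
        P = rng.uniform(size=(10, 4))
        np.testing.assert_array_equal(normalize_frames(P, "none"), P)

    def test_unit_norms(self, rng):
        P = rng.uniform(0.1, 5.0, size=(30, 6))
        np.testing.assert_allclose(
            np.abs(normalize_frames(P, "l1")).sum(axis=0), 1.0
        )
        np.testing.assert_allclose(
            np.linalg.norm(normalize_frames(P, "l2"), axis=0), 1.0
        )

    def test_zero_frame_rejected(self):
        P = np.array([[1.0, 0.0], [1.0, 0.0]])
        with pytest.raises(ValueError, match="all-zero"):
            normalize_frames(P, "l2")
        with pytest.raises(ValueError, match="normalization mode"):
            normalize_frames(P, "weird")


class TestKernelMatrix:
    def test_identical_frames_give_one(self):
        P = np.ones((5, 3))
        np.testing.assert_allclose(kernel_matrix(P, 0.5), 1.0)

    def test_forced_exponent(self):
        sigma = 0.7
        p = np.zeros((2, 2))
        p[0, 1] = np.sqrt(2.0) * sigma      # squared distance = 2 sigma^2
        C = kernel_matrix(p, sigma)
        assert C[0, 1] == pytest.approx(np.exp(-1.0), rel=1e-12)

    def test_matches_direct_evaluation(self, rng):
        P = rng.normal(size=(50, 4))
        C = kernel_matrix(P, 0.9)
        for i in range(4):
            for j in range(4):
                want = np.exp(-np.sum((P[:, i] - P[:, j]) ** 2) / (2 * 0.9**2))
                assert C[i, j] == pytest.approx(want, abs=1e-14)

    def test_sigma_validation(self):
        with pytest.raises(ValueError):
            kernel_matrix(np.ones((3, 2)), 0.0)


class TestLinearKernel:
    def test_orthogonal_frames(self):
        P = np.eye(4)[:, :2]
        C = linear_kernel_matrix(P)
        assert C[0, 1] == 0.0
        assert C[0, 0] == pytest.approx(1.0)

    def test_matches_product_oracle(self, rng):
        P = rng.normal(size=(20, 5))
        np.testing.assert_allclose(linear_kernel_matrix(P), P.T @ P, atol=1e-12)


class TestCenterKernel:
    def test_constant_matrix_centers_to_zero(self):
        np.testing.assert_allclose(center_kernel(np.full((4, 4), 3.0)), 0.0, atol=1e-12)

    def test_two_by_two_hand_value(self):
        c = 0.4
        C_hat = center_kernel(np.array([[1.0, c], [c, 1.0]]))
        w = (1 - c) / 2
        np.testing.assert_allclose(C_hat, [[w, -w], [-w, w]], atol=1e-14)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(arrays(float, (6, 6), elements=st.floats(-5, 5)))
    def test_row_and_column_sums_vanish(self, A):
        C_hat = center_kernel(0.5 * (A + A.T))
        np.testing.assert_allclose(C_hat.sum(axis=0), 0.0, atol=1e-11)
        np.testing.assert_allclose(C_hat.sum(axis=1), 0.0, atol=1e-11)

    def test_non_square_rejected(self):
        with pytest.raises(ValueError, match="square"):
            center_kernel(np.ones((2, 3)))


class TestKernelPcaScores:
    def test_duplicate_frames_share_scores(self, rng):
        P = rng.uniform(size=(40, 5))
        P[:, 3] = P[:, 1]
        C_hat = center_kernel(kernel_matrix(normalize_frames(P, "l2"), 0.5))
        Y, _, _ = kernel_pca_scores(C_hat, 3)
        np.testing.assert_allclose(Y[:, 3], Y[:, 1], atol=1e-9)

    def test_linear_kernel_equals_classical_pca(self, rng):
        """Gram-matrix eigendecomposition reproduces covariance PCA scores."""
        P = rng.normal(size=(60, 8))
        C_hat = center_kernel(linear_kernel_matrix(P))
        Y, _, _ = kernel_pca_scores(C_hat, 4, scaling="whiten")
        # covariance-eigendecomposition oracle on mean-centered data
        Xc = P - P.mean(axis=1, keepdims=True)
        _, _, Vt = np.linalg.svd(Xc.T, full_matrices=False)
        proj = (Xc.T @ Vt[:4].T).T                 # classical PCA projections
        proj /= proj.std(axis=1, ddof=0, keepdims=True)
        for l in range(4):
            diff = min(
                np.max(np.abs(Y[l] - proj[l])), np.max(np.abs(Y[l] + proj[l]))
            )
            assert diff < 1e-8

    def test_component_scaling_preserves_spectrum(self, rng):
        P = rng.normal(size=(30, 6))
        C_hat = center_kernel(kernel_matrix(P, 2.0))
        Y, evals, _ = kernel_pca_scores(C_hat, 6, scaling="component")
        np.testing.assert_allclose(np.trace(Y @ Y.T), evals.sum(), rtol=1e-8)

    def test_raw_scaling_is_centered_gram_projection(self, rng):
        P = rng.normal(size=(30, 6))
        C_hat = center_kernel(kernel_matrix(P, 2.0))
        Y, _, evecs = kernel_pca_scores(C_hat, 3, scaling="raw")
        np.testing.assert_allclose(Y, evecs.T @ C_hat, atol=1e-12)

    def test_d_out_of_range(self):
        C_hat = center_kernel(np.eye(4))
        with pytest.raises(ValueError, match="d must be"):
            kernel_pca_scores(C_hat, 5)

    def test_negative_eigenvalue_rejected(self):
        bad = np.array([[0.0, 1.0], [1.0, 0.0]])   # eigenvalues +-1
        with pytest.raises(ValueError, match="negative"):
            kernel_pca_scores(bad, 2)


class TestAdaptiveK:
    def test_equal_energy_gives_full_k(self, rng):
        P = np.tile(rng.uniform(size=(30, 1)), (1, 24))
        np.testing.assert_array_equal(adaptive_k(P), 24)

    def test_rounding_arithmetic(self):
        N = 24
        P = np.zeros((1, N))
        P[0, :] = 1.0
        P[0, 0] = 0.3          # ratio 0.3 -> r(7.2) = 7
        P[0, 1] = 0.02         # ratio 0.02 -> r(0.48) = 0 -> clamped to 1
        k = adaptive_k(P)
        assert k[0] == 7
        assert k[1] == 1
        assert k[-1] == N

    def test_monotone_when_energies_monotone(self, rng):
        P = growing_sinogram_set(rng)
        k = adaptive_k(P)
        norms = np.abs(P).sum(axis=0)
        assert np.all(np.diff(k[np.argsort(norms, kind="stable")]) >= 0)
        assert k[-1] == P.shape[1]

    def test_zero_final_frame(self):
        with pytest.raises(ValueError, match="final frame"):
            adaptive_k(np.array([[1.0, 0.0]]))


class TestKnnAdjacency:
    def test_self_similarity_is_one(self, rng):
        Y = rng.normal(size=(3, 8))
        A = knn_adjacency(Y, np.full(8, 3), 1.0)
        np.testing.assert_array_equal(np.diag(A), 1.0)

    def test_coincident_neighbor_weight_one(self):
        Y = np.array([[0.0, 0.0, 5.0]])
        A = knn_adjacency(Y, np.array([2, 2, 1]), 1.0)
        assert A[0, 1] == pytest.approx(1.0)

    def test_collinear_pattern_matches_bruteforce(self):
        Y = np.array([[0.0, 1.0, 2.0, 3.0, 4.0]])
        k = np.full(5, 3)
        A = knn_adjacency(Y, k, 2.0)
        for i in range(5):
            d = (Y[0] - Y[0, i]) ** 2
            order = np.argsort(d, kind="stable")
            neighbors = set(order[:3])
            assert set(np.flatnonzero(A[i])) == neighbors

    def test_row_support_counts(self, rng):
        Y = rng.normal(size=(4, 10))
        k = rng.integers(1, 11, size=10)
        A = knn_adjacency(Y, k, 1.0)
        np.testing.assert_array_equal((A > 0).sum(axis=1), k)

    def test_validation(self, rng):
        Y = rng.normal(size=(2, 4))
        with pytest.raises(ValueError):
            knn_adjacency(Y, np.full(4, 2), 0.0)
        with pytest.raises(ValueError):
            knn_adjacency(Y, np.full(4, 9), 1.0)


class TestMarkovTransition:
    def test_identity(self):
        np.testing.assert_array_equal(markov_transition(np.eye(3)), np.eye(3))

    def test_hand_normalization(self):
        A = np.array([[1.0, 0.5], [0.5, 1.0]])
        F = markov_transition(A)
        np.testing.assert_allclose(F, [[2 / 3, 1 / 3], [1 / 3, 2 / 3]])

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(arrays(float, (7, 7), elements=st.floats(0, 10)))
    def test_columns_sum_to_one(self, A):
        np.fill_diagonal(A, 1.0)
        F = markov_transition(A)
        np.testing.assert_allclose(F.sum(axis=0), 1.0, atol=1e-12)

    def test_zero_profile_rejected(self):
        A = np.array([[0.0, 0.0], [1.0, 1.0]])
        with pytest.raises(ValueError, match="nonzero similarity"):
            markov_transition(A)


def random_transition(rng, N=12):
    A = rng.uniform(size=(N, N)) * (rng.uniform(size=(N, N)) < 0.5)
    np.fill_diagonal(A, 1.0)
    return markov_transition(A)


class TestOptimalOrder:
    def test_identity_filter_stops_at_one(self, rng):
        P = rng.uniform(size=(9, 4))
        assert optimal_order(P, np.eye(4), 1e-3, 50) == 1

    def test_loose_epsilon_stops_at_one(self, rng):
        P = rng.uniform(size=(9, 6))
        F = random_transition(rng, 6)
        assert optimal_order(P, F, 1e6, 50) == 1

    def test_matches_exhaustive_scan(self, rng):
        for _ in range(10):
            P = rng.uniform(size=(15, 12))
            F = random_transition(rng)
            got = optimal_order(P, F, 1e-3, 50)
            # brute-force scan of the stopping rule
            best = 50
            for m in range(1, 51):
                prev = P @ np.linalg.matrix_power(F, m - 1)
                cur = prev @ F
                if np.sum((cur - prev) ** 2) / np.sum(prev**2) <= 1e-3:
                    best = m
                    break
            assert got == best

    def test_cap_warns(self, rng):
        P = rng.uniform(size=(6, 5))
        F = random_transition(rng, 5)
        with pytest.warns(UserWarning, match="cap"):
            m = optimal_order(P, F, 1e-30, 4)
        assert m == 4


class TestApplyGraphFilter:
    def test_identity(self, rng):
        P = rng.uniform(size=(7, 5))
        np.testing.assert_array_equal(apply_graph_filter(P, np.eye(5), 3), P)

    def test_order_two_is_twice_order_one(self, rng):
        P = rng.uniform(size=(7, 5))
        F = random_transition(rng, 5)
        once = apply_graph_filter(apply_graph_filter(P, F, 1), F, 1)
        np.testing.assert_allclose(apply_graph_filter(P, F, 2), once, atol=1e-12)

    def test_hand_product(self):
        P = np.array([[1.0, 2.0, 4.0]])
        F = np.array([[0.5, 0.0, 0.25], [0.5, 1.0, 0.25], [0.0, 0.0, 0.5]])
        np.testing.assert_allclose(apply_graph_filter(P, F, 1), [[1.5, 2.0, 2.75]])

    def test_convex_combination_bound(self, rng):
        P = rng.uniform(size=(20, 10)) * np.linspace(1, 50, 10)
        F = random_transition(rng, 10)
        out = apply_graph_filter(P, F, 4)
        lo, hi = P.min(axis=1, keepdims=True), P.max(axis=1, keepdims=True)
        assert np.all(out >= lo - 1e-10) and np.all(out <= hi + 1e-10)
        l1 = np.abs(P).sum(axis=0)
        out_l1 = np.abs(out).sum(axis=0)
        assert np.all(out_l1 >= l1.min() - 1e-8) and np.all(out_l1 <= l1.max() + 1e-8)

    def test_dimension_mismatch(self, rng):
        with pytest.raises(ValueError, match="frame count"):
            apply_graph_filter(np.ones((4, 3)), np.eye(5), 1)


class TestStochasticityAndConvergence:
    def test_powers_remain_column_stochastic(self, rng):
        F = random_transition(rng)
        M = np.eye(F.shape[0])
        for _ in range(50):
            M = M @ F
            np.testing.assert_allclose(M.sum(axis=0), 1.0, atol=1e-12)

    def test_high_order_converges_to_common_average(self, rng):
        """Connected aperiodic graph: all filtered frames merge (over-correlation)."""
        A = np.ones((5, 5)) * 0.3
        np.fill_diagonal(A, 1.0)
        F = markov_transition(A)
        P = rng.uniform(size=(8, 5)) * np.arange(1, 6)
        out = apply_graph_filter(P, F, 400)
        np.testing.assert_allclose(
            out, np.broadcast_to(out[:, :1], out.shape), rtol=1e-8
        )


class TestDenoiserPipeline:
    def test_identical_frames_pass_through(self):
        P = np.tile(np.linspace(1, 2, 40)[:, None], (1, 24))
        res = kp.KernelGraphDenoiser(P).fit()
        np.testing.assert_allclose(res.denoised_array, P, rtol=1e-10)
        assert res.m_star == 1

    def test_defaults_run_end_to_end(self, rng):
        P = growing_sinogram_set(rng)
        res = kp.KernelGraphDenoiser(P).fit()
        assert res.denoised_array.shape == P.shape
        assert res.m_star >= 1
        assert "m*" in res.summary() and "gaussian" in res.summary()

    def test_count_preservation(self, rng):
        P = growing_sinogram_set(rng)
        res = kp.KernelGraphDenoiser(P).fit()
        np.testing.assert_allclose(
            res.denoised_array.sum(axis=0), P.sum(axis=0), rtol=1e-10
        )

    def test_literal_filtering_mode(self, rng):
        """count_preserving=False applies P F^m to the raw counts."""
        P = growing_sinogram_set(rng)
        res = kp.KernelGraphDenoiser(P, count_preserving=False).fit()
        fm = res.filter_model
        want = apply_graph_filter(P, fm.F, fm.m_star)
        np.testing.assert_allclose(res.denoised_array, want, atol=1e-10)

    def test_linear_kernel_variant(self, rng):
        P = growing_sinogram_set(rng)
        res = kp.KernelGraphDenoiser(P, kernel_kind="linear", d=10).fit()
        assert res.embedding.kernel_kind == "linear"
        assert res.embedding.sigma1 is None

    def test_container_round_trip(self, rng):
        from kgfpet.schedule import fdg_24frame_schedule

        P = growing_sinogram_set(rng, M=6 * 10, N=24)
        s = kp.DynamicSinogramSet(
            P=P, n_bins=6, n_angles=10, schedule=fdg_24frame_schedule(),
            provenance="noisy",
        )
        out = kp.KernelGraphDenoiser(s).fit().denoised
        assert isinstance(out, kp.DynamicSinogramSet)
        assert out.provenance == "denoised"
        assert out.meta["denoiser"]["m_star"] >= 1

    def test_zero_frame_rejected(self):
        P = np.ones((5, 4))
        P[:, 0] = 0.0
        with pytest.raises(ValueError, match="zero-count"):
            kp.KernelGraphDenoiser(P)

    def test_invivo_profile(self):
        cfg = KGFConfig.invivo()
        assert (cfg.d, cfg.sigma1, cfg.sigma2, cfg.epsilon) == (8, 0.15, 0.5, 1e-4)
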