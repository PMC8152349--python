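"""Manifold optimization: objective, gradient, projection, retraction, loop."""

import numpy as np
import pytest
import scipy.linalg

from mcsm.graph import JointLaplacian, ViewGraph, joint_laplacian
from mcsm.optimizer import (
    OptParams,
    StackedEmbedding,
    backtracking_step,
    negative_gradient,
    objective,
    optimize,
    svd_retract,
    tangent_project,
)
from tests.conftest import random_orthonormal

import scipy.sparse as sp


def joint_from_dense(L_dense, M=1, beta=0.0):
    """Wrap a dense symmetric matrix as a single-view JointLaplacian."""
    Ls = sp.csr_matrix(L_dense)
    return JointLaplacian(L=Ls, beta=beta, M=M, N=L_dense.shape[0] // M, view_laplacians=[Ls])


class TestObjective:
    def test_zero_matrix(self, rng):
        J = joint_from_dense(np.zeros((6, 6)))
        U = StackedEmbedding([random_orthonormal(rng, 6, 2)])
        assert objective(U, J) == 0.0

    def test_laplacian_nullspace_constant_vector(self):
        W = np.ones((3, 3)) - np.eye(3)
        g = ViewGraph.from_adjacency(W)
        J = joint_laplacian([g])
        U = StackedEmbedding([np.full((3, 1), 1 / np.sqrt(3))])
        assert objective(U, J) == pytest.approx(0.0, abs=1e-12)

    def test_matches_elementwise_oracle(self, rng):
        A = rng.standard_normal((6, 6))
        L = (A + A.T) / 2
        U = StackedEmbedding([random_orthonormal(rng, 6, 2)])
        got = objective(U, joint_from_dense(L))
        UUt = U.blocks[0] @ U.blocks[0].T
        brute = sum(L[i, j] * UUt[i, j] for i in range(6) for j in range(6))
        assert got == pytest.approx(brute)

    def test_decomposes_into_view_and_coupling_terms(self, rng, joint_sbm30):
        J = joint_sbm30
        blocks = [random_orthonormal(rng, J.N, 3) for _ in range(J.M)]
        U = StackedEmbedding(blocks)
        per_view = sum(
            np.trace(b.T @ Lm.toarray() @ b) for b, Lm in zip(blocks, J.view_laplacians)
        )
        coupling = sum(
            np.trace(blocks[m].T @ blocks[l])
            for m in range(J.M)
            for l in range(J.M)
            if l != m
        )
        assert objective(U, J) == pytest.approx(per_view - J.beta * coupling)


class TestGradient:
    def test_zero_matrix_gives_zero(self, rng):
        J = joint_from_dense(np.zeros((5, 5)))
        U = StackedEmbedding([random_orthonormal(rng, 5, 2)])
        assert np.all(negative_gradient(U, J) == 0)

    def test_coupling_only_gradient_swaps_blocks(self, rng):
        g = ViewGraph.from_adjacency(np.zeros((4, 4)))
        J = joint_laplacian([g, g], beta=1.0)
        U1, U2 = random_orthonormal(rng, 4, 2), random_orthonormal(rng, 4, 2)
        Z = negative_gradient(StackedEmbedding([U1, U2]), J)
        # L has only −I coupling blocks, so −2LU = 2(U2; U1)
        np.testing.assert_allclose(Z[:4], 2 * U2, atol=1e-12)
        np.testing.assert_allclose(Z[4:], 2 * U1, atol=1e-12)

    @pytest.mark.parametrize("trial", range(3))
    def test_finite_difference_directional_derivative(self, rng, trial):
        A = rng.standard_normal((8, 8))
        L = (A + A.T) / 2
        J = joint_from_dense(L)
        U = StackedEmbedding([random_orthonormal(rng, 8, 2)])
        Z = negative_gradient(U, J)
        H = tangent_project(U.blocks[0], rng.standard_normal((8, 2)))
        eps = 1e-6
        f = lambda M: float(np.sum(M * (L @ M)))  # noqa: E731
        fd = (f(U.blocks[0] + eps * H) - f(U.blocks[0] - eps * H)) / (2 * eps)
        assert fd == pytest.approx(-np.sum(Z * H), abs=1e-5)


class TestTangentProject:
    def test_normal_direction_annihilated(self, rng):
        U = random_orthonormal(rng, 6, 2)
        np.testing.assert_allclose(tangent_project(U, U), 0.0, atol=1e-12)

    def test_tangent_input_unchanged(self, rng):
        U = random_orthonormal(rng, 6, 2)
        eta = tangent_project(U, rng.standard_normal((6, 2)))
        np.testing.assert_allclose(tangent_project(U, eta), eta, atol=1e-10)

    def test_result_satisfies_skew_condition(self, rng):
        U = random_orthonormal(rng, 6, 2)
        eta = tangent_project(U, rng.standard_normal((6, 2)))
        skew = U.T @ eta
        np.testing.assert_allclose(skew + skew.T, 0.0, atol=1e-10)

    def test_non_orthonormal_rejected(self, rng):
        with pytest.raises(ValueError, match="orthonormal"):
            tangent_project(np.ones((4, 2)), np.zeros((4, 2)))

    def test_literal_printed_variant_is_not_tangent(self, rng):
        U = random_orthonormal(rng, 6, 2)
        Z = rng.standard_normal((6, 2))
        eta = tangent_project(U, Z, literal=True)
        skew = U.T @ eta
        assert np.abs(skew + skew.T).max() > 1e-3  # the typo'd formula leaves the tangent space


class TestSvdRetract:
    def test_orthonormal_fixed_point(self, rng):
        Q = random_orthonormal(rng, 5, 3)
        np.testing.assert_allclose(svd_retract(Q), Q, atol=1e-10)

    def test_positive_scaling_removed(self):
        np.testing.assert_allclose(svd_retract(2 * np.eye(2)), np.eye(2), atol=1e-12)

    def test_polar_factor_is_nearest_orthonormal(self, rng):
        Y = rng.standard_normal((5, 2))
        P = svd_retract(Y)
        np.testing.assert_allclose(P.T @ P, np.eye(2), atol=1e-12)
        best = np.linalg.norm(P - Y)
        for _ in range(200):
            Q = random_orthonormal(rng, 5, 2)
            assert np.linalg.norm(Q - Y) >= best - 1e-12

    def test_rank_deficient_rejected(self):
        Y = np.zeros((4, 2))
        Y[:, 0] = 1.0
        with pytest.raises(np.linalg.LinAlgError):
            svd_retract(Y)


class TestBacktracking:
    def test_zero_direction_accepts_immediately(self, rng, joint_sbm30):
        U, _ = optimize(joint_sbm30, 2, OptParams(max_iter=1))
        eta = [np.zeros_like(b) for b in U.blocks]
        Z = negative_gradient(U, joint_sbm30)
        alpha, U_next, ok = backtracking_step(U, eta, Z, joint_sbm30, OptParams())
        assert ok and alpha == OptParams().alpha0
        for b, b2 in zip(U.blocks, U_next.blocks):
            np.testing.assert_allclose(b, b2, atol=1e-10)

    def test_descent_on_unit_circle(self):
        # K=1, N=2 Stiefel is the circle; minimize x^T diag(0, 2) x
        L = np.diag([0.0, 2.0])
        J = joint_from_dense(L)
        theta = 1.0
        U = StackedEmbedding([np.array([[np.cos(theta)], [np.sin(theta)]])])
        f0 = objective(U, J)
        Z = negative_gradient(U, J)
        eta = [tangent_project(U.blocks[0], Z)]
        alpha, U_next, ok = backtracking_step(U, eta, Z, J, OptParams(), f0=f0)
        assert ok and alpha > 0
        assert objective(U_next, J) < f0

    def test_ascent_direction_returns_no_progress(self, rng, joint_sbm30):
        U, _ = optimize(joint_sbm30, 2, OptParams(max_iter=1))
        Z = negative_gradient(U, joint_sbm30)
        # deliberately walk uphill: the positive gradient direction
        eta = [
            tangent_project(u, -z)
            for u, z in zip(U.blocks, np.split(Z, joint_sbm30.M))
        ]
        f0 = objective(U, joint_sbm30)
        alpha, U_next, ok = backtracking_step(U, eta, Z, joint_sbm30, OptParams(), f0=f0)
        if not ok:
            assert alpha == 0.0
            assert objective(U_next, joint_sbm30) == pytest.approx(f0)


class TestOptimize:
    def test_single_view_matches_bottom_eigenvectors(self, sbm30):
        g = ViewGraph.from_adjacency(sbm30.adjacencies[0])
        J = joint_laplacian([g])
        U, _ = optimize(J, 3)
        _, vecs = scipy.linalg.eigh(g.L.toarray(), subset_by_index=[0, 2])
        angles = scipy.linalg.subspace_angles(U.blocks[0], vecs)
        assert angles.max() < 1e-3

    def test_identical_views_converge_to_matching_subspaces(self, sbm30):
        g = ViewGraph.from_adjacency(sbm30.adjacencies[0])
        J = joint_laplacian([g, g], beta=1.0)
        U, _ = optimize(J, 3)
        angles = scipy.linalg.subspace_angles(U.blocks[0], U.blocks[1])
        assert angles.max() < 1e-2

    def test_monotone_descent_and_feasibility(self, joint_sbm30):
        U, trace = optimize(joint_sbm30, 3)
        f = np.array(trace.objective_per_iter)
        assert (np.diff(f) <= 1e-10).all()
        assert U.feasibility() < 1e-8

    def test_random_init_descends_toward_spectral_value(self, joint_sbm30):
        params = OptParams(alpha0=0.5, max_iter=2000, seed=3)
        U_r, tr_r = optimize(joint_sbm30, 3, params, init="random")
        U_s, tr_s = optimize(joint_sbm30, 3)
        assert tr_r.objective_per_iter[-1] < tr_r.objective_per_iter[0]
        # a long random-init run reaches the warm-started optimum
        assert tr_r.objective_per_iter[-1] <= tr_s.objective_per_iter[-1] + 0.5

    def test_deterministic_given_seed(self, joint_sbm30):
        U1, _ = optimize(joint_sbm30, 3, OptParams(seed=4), init="random")
        U2, _ = optimize(joint_sbm30, 3, OptParams(seed=4), init="random")
        for a, b in zip(U1.blocks, U2.blocks):
            np.testing.assert_array_equal(a, b)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            OptParams(alpha0=-1)
        with pytest.raises(ValueError):
            OptParams(tau=1.5)
        with pytest.raises(ValueError):
            OptParams(armijo="bogus")
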