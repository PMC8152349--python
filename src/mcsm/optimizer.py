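"""Minimization of trace(UᵀLU) over a product of Stiefel manifolds.

The relaxed multi-view spectral clustering problem is

    min_{U_m} trace(UᵀLU)   s.t.  U_mᵀU_m = I_K  for every view m,

with U the vertical stack of the per-view embeddings U_m and L the joint
block Laplacian.  It is solved by projected gradient descent on the product
manifold: the Euclidean negative gradient Z = −2LU is projected onto each
tangent space, a backtracking (Armijo) line search picks the step size, and
the stepped point is retracted back to the manifold through the polar
factor of its thin SVD.

The sufficient-decrease condition is evaluated at the retracted candidate,

    f(R(U + αη)) ≤ f(U) − α · c_eff · ⟨η, Z⟩,

with c_eff = min(c, 0.99): a slope coefficient above 1 demands more descent
than the linearization provides and can never be satisfied for small steps,
so the configured control parameter c (default 6) is capped while still
being exposed for the literal variant (``armijo="literal"``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .graph import JointLaplacian

__all__ = [
    "StackedEmbedding",
    "OptParams",
    "OptTrace",
    "objective",
    "negative_gradient",
    "tangent_project",
    "svd_retract",
    "backtracking_step",
    "optimize",
]

logger = logging.getLogger(__name__)

_ORTHO_TOL = 1e-8


@dataclass
class StackedEmbedding:
    """Vertical stack of M per-view N × K column-orthonormal blocks."""

    blocks: list[np.ndarray]

    @property
    def M(self) -> int:
        return len(self.blocks)

    @property
    def N(self) -> int:
        return self.blocks[0].shape[0]

    @property
    def K(self) -> int:
        return self.blocks[0].shape[1]

    def stacked(self) -> np.ndarray:
        return np.vstack(self.blocks)

    @classmethod
    def from_stacked(cls, arr: np.ndarray, M: int) -> "StackedEmbedding":
        if arr.shape[0] % M:
            raise ValueError("stacked array rows not divisible by view count")
        return cls(list(np.split(np.asarray(arr, dtype=float), M, axis=0)))

    def feasibility(self) -> float:
        """Largest ‖U_mᵀU_m − I‖_F over views (0 on the manifold)."""
        k = self.K
        return max(np.linalg.norm(b.T @ b - np.eye(k)) for b in self.blocks)


@dataclass
class OptParams:
    """Line-search and stopping parameters.

    alpha0 is the initial step, c the Armijo control parameter, tau the
    geometric shrink factor, and tol the relative objective-change
    threshold.  ``armijo`` selects the capped sufficient-decrease condition
    (default) or the condition with the raw c (``"literal"``).
    """

    alpha0: float = 0.01
    c: float = 6.0
    tau: float = 0.1
    max_iter: int = 20
    tol: float = 1e-6
    max_backtracks: int = 30
    seed: int = 0
    armijo: str = "capped"

    def __post_init__(self) -> None:
        if self.alpha0 <= 0:
            raise ValueError("alpha0 must be positive")
        if not 0 < self.tau < 1:
            raise ValueError("tau must lie in (0, 1)")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.armijo not in ("capped", "literal"):
            raise ValueError("armijo must be 'capped' or 'literal'")


@dataclass
class OptTrace:
    """Objective values and accepted step sizes per iteration."""

    objective_per_iter: list = field(default_factory=list)
    step_sizes: list = field(default_factory=list)
    converged: bool = False


def objective(U: StackedEmbedding, L: JointLaplacian) -> float:
    """trace(UᵀLU) for the stacked embedding."""
    Us = U.stacked()
    if Us.shape[0] != L.shape[0]:
        raise ValueError("embedding rows do not match Laplacian dimension")
    val = float(np.sum(Us * (L.L @ Us)))
    if not np.isfinite(val):
        raise FloatingPointError("non-finite objective value")
    return val


def negative_gradient(U: StackedEmbedding, L: JointLaplacian) -> np.ndarray:
    """Euclidean negative gradient Z = −2LU, stacked MN × K."""
    Us = U.stacked()
    if Us.shape[0] != L.shape[0]:
        raise ValueError("embedding rows do not match Laplacian dimension")
    return -2.0 * (L.L @ Us)


def tangent_project(U_m: np.ndarray, Z_m: np.ndarray, literal: bool = False) -> np.ndarray:
    """Project Z_m onto the tangent space of the Stiefel manifold at U_m.

    η_m = Z_m − ½ U_m (U_mᵀZ_m + Z_mᵀU_m), which satisfies the tangency
    condition U_mᵀη_m + η_mᵀU_m = 0.  The ``literal`` variant replaces
    U_mᵀZ_m by U_mᵀU_m (debug only; the result is generally not tangent).
    """
    k = U_m.shape[1]
    if np.linalg.norm(U_m.T @ U_m - np.eye(k)) > 1e-6:
        raise ValueError("U_m must have orthonormal columns")
    inner = (U_m.T @ U_m if literal else U_m.T @ Z_m) + Z_m.T @ U_m
    return Z_m - 0.5 * U_m @ inner


def svd_retract(Y: np.ndarray) -> np.ndarray:
    """Closest orthonormal matrix to Y (polar factor of the thin SVD)."""
    W, s, Vt = np.linalg.svd(Y, full_matrices=False)
    if s[-1] <= max(Y.shape) * np.finfo(float).eps * s[0]:
        raise np.linalg.LinAlgError("rank-deficient matrix cannot be retracted")
    return W @ Vt


def _retract_all(blocks: list[np.ndarray]) -> StackedEmbedding:
    return StackedEmbedding([svd_retract(b) for b in blocks])


def backtracking_step(
    U: StackedEmbedding,
    eta: list[np.ndarray],
    Z: np.ndarray,
    L: JointLaplacian,
    params: OptParams,
    f0: float | None = None,
):
    """Armijo backtracking along the tangent direction eta with retraction.

    Tries α ∈ {α₀, τα₀, τ²α₀, …} and accepts the first retracted candidate
    satisfying the sufficient-decrease condition.  Returns
    ``(alpha, U_next, accepted)``; when ``max_backtracks`` is exhausted the
    original point is returned with α = 0 and ``accepted=False``.
    """
    if f0 is None:
        f0 = objective(U, L)
    Zb = np.split(Z, U.M, axis=0)
    # ⟨η, Z⟩ = ‖η‖² ≥ 0 when η is the projected negative gradient; the
    # absolute value guards against a caller-supplied ascent direction
    slope = abs(sum(float(np.sum(e * z)) for e, z in zip(eta, Zb)))
    c_eff = params.c if params.armijo == "literal" else min(params.c, 0.99)
    alpha = params.alpha0
    for _ in range(params.max_backtracks):
        cand = _retract_all([u + alpha * e for u, e in zip(U.blocks, eta)])
        f_cand = objective(cand, L)
        if f_cand <= f0 - alpha * c_eff * slope + 1e-12 * max(1.0, abs(f0)):
            return alpha, cand, True
        alpha *= params.tau
    return 0.0, U, False


def _bottom_eigvecs(A, K: int) -> np.ndarray:
    """K smallest-eigenvalue eigenvectors of a sparse symmetric matrix.

    Computed as the K largest of cI − A with c a Gershgorin bound on the
    spectrum, which keeps ARPACK in its well-conditioned regime and needs
    only matrix-vector products.  Small problems use a dense solver.
    """
    A = sp.csr_matrix(A)
    n = A.shape[0]
    if n <= 600 or K >= n - 1:
        _, vecs = scipy.linalg.eigh(A.toarray(), subset_by_index=[0, min(K, n) - 1])
        return vecs[:, :K]
    c = float(abs(A).sum(axis=1).max()) + 1.0
    vals, vecs = spla.eigsh(sp.identity(n, format="csr") * c - A, k=K, which="LA")
    return vecs[:, np.argsort(c - vals)]


def _joint_spectral_init(L: JointLaplacian, K: int) -> StackedEmbedding:
    """Warm start from the joint matrix's own bottom-K eigenvectors.

    The classical relaxation with the single constraint UᵀU = I is solved
    exactly by these eigenvectors; splitting them into view blocks and
    retracting each block to its Stiefel manifold yields a feasible point
    already close to the coupled optimum, so a few polishing iterations
    suffice.  With one view this reduces to the spectral-clustering
    embedding of L_1.
    """
    vecs = _bottom_eigvecs(L.L, K)
    return _retract_all(list(np.split(vecs, L.M, axis=0)))


def _per_view_spectral_init(L: JointLaplacian, K: int) -> StackedEmbedding:
    """Warm start from the K smallest eigenvectors of each L_m separately.

    Ignores the coupling term: each block starts at its own view's
    spectral-clustering solution, which can be far from the joint optimum
    when β > 0.
    """
    return StackedEmbedding(
        [np.ascontiguousarray(_bottom_eigvecs(Lm, K)) for Lm in L.view_laplacians]
    )


def _random_init(L: JointLaplacian, K: int, seed: int) -> StackedEmbedding:
    rng = np.random.default_rng(seed)
    blocks = []
    for _ in range(L.M):
        q, _ = np.linalg.qr(rng.standard_normal((L.N, K)))
        blocks.append(q)
    return StackedEmbedding(blocks)


def optimize(
    L: JointLaplacian,
    K: int,
    params: OptParams | None = None,
    init: str | StackedEmbedding = "spectral",
):
    """Run the projected-gradient / backtracking / retraction loop.

    Iterates gradient → tangent projection → line search → SVD retraction
    until ``max_iter`` or the relative objective change falls below ``tol``.
    Non-convergence is reported in the trace, never raised.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    params = params or OptParams()
    if isinstance(init, StackedEmbedding):
        U = init
    elif init == "spectral":
        U = _joint_spectral_init(L, K)
    elif init == "spectral_per_view":
        U = _per_view_spectral_init(L, K)
    elif init == "random":
        U = _random_init(L, K, params.seed)
    else:
        raise ValueError(
            "init must be 'spectral', 'spectral_per_view', 'random' or a StackedEmbedding"
        )
    if U.feasibility() > _ORTHO_TOL:
        U = _retract_all(U.blocks)

    trace = OptTrace()
    f = objective(U, L)
    trace.objective_per_iter.append(f)
    for it in range(params.max_iter):
        Z = negative_gradient(U, L)
        eta = [
            tangent_project(u, z) for u, z in zip(U.blocks, np.split(Z, U.M, axis=0))
        ]
        alpha, U_next, accepted = backtracking_step(U, eta, Z, L, params, f0=f)
        f_next = objective(U_next, L) if accepted else f
        trace.step_sizes.append(alpha)
        trace.objective_per_iter.append(min(f_next, f))
        logger.info("iter %d: objective=%.6g alpha=%.3g", it + 1, f_next, alpha)
        if not accepted:
            trace.converged = True  # no descent direction makes progress
            break
        rel = abs(f - f_next) / max(1.0, abs(f))
        U, f = U_next, f_next
        if rel < params.tol:
            trace.converged = True
            break
    return U, trace
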