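"""Per-view similarity graphs, Laplacians and the joint block Laplacian.

For each omic a patient-to-patient similarity graph is built from a heat
(Gaussian) kernel sparsified to a k-nearest-neighbour graph.  The view
Laplacians L_m = D_m − W_m are then assembled into the MN × MN joint matrix

    L = blockdiag(L_1, …, L_M) − β · (off-diagonal identity blocks),

whose trace quadratic form couples the per-view spectral embeddings.
Simulated binary adjacency matrices bypass the kernel and feed
:func:`laplacian` directly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.spatial.distance import pdist, squareform

from .preprocess import OmicsMatrix

__all__ = [
    "ViewGraph",
    "JointLaplacian",
    "heat_kernel",
    "knn_graph",
    "laplacian",
    "joint_laplacian",
]


@dataclass
class ViewGraph:
    """Symmetric weighted adjacency with its degree vector and Laplacian."""

    W: sp.csr_matrix
    degrees: np.ndarray
    L: sp.csr_matrix

    @classmethod
    def from_adjacency(cls, W) -> "ViewGraph":
        """Build degrees and L = D − W from a symmetric nonnegative adjacency.

        Accepts a dense array or sparse matrix; the diagonal is zeroed
        (self-loops cancel in D − W and are dropped for interpretability).
        """
        W = sp.csr_matrix(W, dtype=float)
        if W.shape[0] != W.shape[1]:
            raise ValueError("adjacency must be square")
        if (abs(W - W.T) > 1e-10).nnz:
            raise ValueError("adjacency must be symmetric")
        if W.nnz and W.data.min() < 0:
            raise ValueError("adjacency must be nonnegative")
        W = sp.csr_matrix(W - sp.diags(W.diagonal()))
        W.eliminate_zeros()
        d = np.asarray(W.sum(axis=1)).ravel()
        L = sp.csr_matrix(sp.diags(d) - W)
        return cls(W=W, degrees=d, L=L)

    @property
    def n_nodes(self) -> int:
        return self.W.shape[0]


@dataclass
class JointLaplacian:
    """MN × MN block matrix coupling M view Laplacians with weight beta."""

    L: sp.csr_matrix
    beta: float
    M: int
    N: int
    view_laplacians: list

    @property
    def shape(self):
        return self.L.shape


def heat_kernel(X: OmicsMatrix | np.ndarray, t: float | None = None) -> np.ndarray:
    """Gaussian similarity S_ij = exp(−‖x_i − x_j‖² / 2t²) between samples.

    Columns of ``X`` are samples.  When ``t`` is None it defaults to the
    median off-diagonal pairwise distance (self-tuning bandwidth).
    """
    values = X.values if isinstance(X, OmicsMatrix) else np.asarray(X, dtype=float)
    if np.isnan(values).any():
        raise ValueError("heat_kernel requires a complete matrix")
    d = pdist(values.T)  # condensed pairwise distances between samples
    if t is None:
        t = float(np.median(d))
        if t <= 0:
            raise ValueError("degenerate data: median pairwise distance is zero")
    elif t <= 0:
        raise ValueError("bandwidth t must be positive")
    S = squareform(np.exp(-(d**2) / (2.0 * t**2)))
    np.fill_diagonal(S, 1.0)
    return S


def knn_graph(S: np.ndarray, k_neighbors: int, mode: str = "union") -> ViewGraph:
    """Sparsify a similarity matrix to a symmetric k-nearest-neighbour graph.

    An edge (i, j) is kept when j is among the k most similar nodes of i or
    (``mode="union"``, default) / and (``mode="mutual"``) vice versa.  Ties
    at the k-th neighbour are broken by node index.
    """
    S = np.asarray(S, dtype=float)
    n = S.shape[0]
    if S.shape != (n, n) or not np.allclose(S, S.T, atol=1e-10):
        raise ValueError("S must be square and symmetric")
    if not 1 <= k_neighbors < n:
        raise ValueError("need 1 <= k_neighbors < N")
    if mode not in ("union", "mutual"):
        raise ValueError("mode must be 'union' or 'mutual'")
    rank = -S.copy()
    np.fill_diagonal(rank, -np.inf)  # self always ranks first, then excluded
    order = np.argsort(rank, axis=1, kind="stable")  # stable sort → index tie-break
    mask = np.zeros((n, n), dtype=bool)
    rows = np.repeat(np.arange(n), k_neighbors)
    mask[rows, order[:, 1 : k_neighbors + 1].ravel()] = True
    mask = (mask | mask.T) if mode == "union" else (mask & mask.T)
    W = np.where(mask, S, 0.0)
    np.fill_diagonal(W, 0.0)
    return ViewGraph.from_adjacency(W)


def laplacian(W) -> sp.csr_matrix:
    """Graph Laplacian L = D − W of a symmetric nonnegative adjacency."""
    return ViewGraph.from_adjacency(W).L


def joint_laplacian(views: list[ViewGraph], beta: float = 1.0) -> JointLaplacian:
    """Assemble the joint block Laplacian from per-view graphs.

    Diagonal blocks are the view Laplacians; every off-diagonal block is
    −β·I_N, rewarding agreement between the per-view embeddings.  With a
    single view the coupling term vanishes and L equals L_1.
    """
    if not views:
        raise ValueError("need at least one view")
    n = views[0].n_nodes
    if any(v.n_nodes != n for v in views):
        raise ValueError("all views must share the same node count")
    m = len(views)
    L = sp.block_diag([v.L for v in views], format="csr")
    if m > 1 and beta != 0.0:
        coupling = sp.kron(
            sp.csr_matrix(np.ones((m, m)) - np.eye(m)), sp.identity(n), format="csr"
        )
        L = sp.csr_matrix(L - beta * coupling)
    return JointLaplacian(L=L, beta=float(beta), M=m, N=n, view_laplacians=[v.L for v in views])
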