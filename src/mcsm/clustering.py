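"""From embedding to labels: per-view k-means, K selection, integration.

Each view's embedding block U_m is clustered by k-means (rows normalized to
unit length first, as is standard for spectral embeddings).  Because
k-means labels are arbitrary per view, views are aligned to the first view
by maximum-overlap (Hungarian) matching before the final integration step,
which assigns every sample the majority label over its own and its nearest
neighbours' aligned per-view labels in the concatenated embedding.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy.optimize import linear_sum_assignment
from sklearn.cluster import KMeans
from sklearn.metrics import calinski_harabasz_score
from sklearn.neighbors import NearestNeighbors

from .optimizer import StackedEmbedding

__all__ = [
    "ViewLabels",
    "IntegratedClustering",
    "KSelection",
    "kmeans_per_view",
    "select_k",
    "align_labels",
    "integrate_knn",
]


@dataclass
class ViewLabels:
    """M per-view label vectors (M × N int array) with alignment status."""

    labels: np.ndarray
    aligned: bool = False

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.ndim != 2:
            raise ValueError("labels must be an M × N array")
        if self.labels.shape[0] == 1:
            self.aligned = True

    @property
    def M(self) -> int:
        return self.labels.shape[0]

    @property
    def N(self) -> int:
        return self.labels.shape[1]


@dataclass
class IntegratedClustering:
    """Final labels plus the per-view labels and K-selection diagnostics."""

    final_labels: np.ndarray
    per_view: ViewLabels
    K: int
    ch_scores: dict | None = None


class KSelection(NamedTuple):
    best_k: int
    scores: dict


def _row_normalize(block: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(block, axis=1, keepdims=True)
    norms[norms == 0] = 1.0  # zero rows left untouched
    return block / norms


def _concat_embedding(U: StackedEmbedding, row_normalize: bool = True) -> np.ndarray:
    blocks = [_row_normalize(b) if row_normalize else b for b in U.blocks]
    return np.hstack(blocks)


def kmeans_per_view(
    U: StackedEmbedding,
    K: int,
    seed: int = 0,
    n_init: int = 50,
    row_normalize: bool = True,
) -> ViewLabels:
    """k-means with K clusters on each view's embedding block.

    Deterministic for a fixed seed (k-means++ init, fixed restart count).
    """
    if K < 2:
        raise ValueError("K must be >= 2")
    if K > U.N:
        raise ValueError(f"K={K} exceeds sample count N={U.N}")
    labels = np.empty((U.M, U.N), dtype=int)
    for m, block in enumerate(U.blocks):
        X = _row_normalize(block) if row_normalize else block
        km = KMeans(n_clusters=K, n_init=n_init, init="k-means++", random_state=seed)
        labels[m] = km.fit_predict(X)
    return ViewLabels(labels=labels, aligned=(U.M == 1))


def select_k(
    U: StackedEmbedding,
    k_min: int = 2,
    k_max: int = 10,
    seed: int = 0,
    n_init: int = 50,
    row_normalize: bool = True,
) -> KSelection:
    """Pick the cluster number maximizing the Calinski–Harabasz score.

    k-means is scored on the row-concatenated embedding for each candidate
    K in [k_min, k_max]; ties go to the smallest K.
    """
    if not 2 <= k_min <= k_max:
        raise ValueError("need 2 <= k_min <= k_max")
    if k_max >= U.N:
        raise ValueError("k_max must be < N")
    X = _concat_embedding(U, row_normalize=row_normalize)
    if np.allclose(X, X[0]):
        raise ValueError("degenerate embedding: all samples identical")
    scores: dict[int, float] = {}
    if k_min == k_max:
        return KSelection(k_min, scores)
    best_k, best_score = k_min, -np.inf
    for k in range(k_min, k_max + 1):
        labels = KMeans(n_clusters=k, n_init=n_init, random_state=seed).fit_predict(X)
        score = calinski_harabasz_score(X, labels)
        scores[k] = float(score)
        if score > best_score:  # strict: ties keep the smaller K
            best_k, best_score = k, score
    return KSelection(best_k, scores)


def align_labels(view_labels: ViewLabels) -> ViewLabels:
    """Permute labels of views 2..M to best match view 1.

    Maximum-overlap matching on the pairwise contingency table, solved by
    the Hungarian algorithm.  Required before any cross-view vote; the
    mapping is cross-view plumbing, not part of the clustering model.
    """
    labels = view_labels.labels.copy()
    if view_labels.M == 1:
        return ViewLabels(labels=labels, aligned=True)
    k = int(labels.max()) + 1
    ref = labels[0]
    for m in range(1, labels.shape[0]):
        cont = np.zeros((k, k))
        np.add.at(cont, (labels[m], ref), 1)
        row, col = linear_sum_assignment(-cont)
        mapping = np.empty(k, dtype=int)
        mapping[row] = col
        labels[m] = mapping[labels[m]]
    return ViewLabels(labels=labels, aligned=True)


def integrate_knn(
    U: StackedEmbedding,
    view_labels: ViewLabels,
    k_integrate: int = 10,
) -> IntegratedClustering:
    """Fuse aligned per-view labels by a k-nearest-neighbour majority vote.

    Each sample's final label is the majority over the M·(k+1) aligned
    labels of itself and its k nearest neighbours in the concatenated
    embedding.  Ties are broken by the sample's own majority view label,
    then by the smallest label index.
    """
    if not view_labels.aligned:
        raise ValueError("view labels must be aligned before integration")
    if k_integrate < 1:
        raise ValueError("k_integrate must be >= 1")
    n = view_labels.N
    if k_integrate >= n:
        warnings.warn(f"k_integrate={k_integrate} >= N={n}; clamping to {n - 1}", stacklevel=2)
        k_integrate = n - 1
    X = _concat_embedding(U)
    nn = NearestNeighbors(n_neighbors=k_integrate + 1).fit(X)
    _, idx = nn.kneighbors(X)
    # guarantee self-inclusion even when duplicate points shadow the query
    for i in range(n):
        if i not in idx[i]:
            idx[i, -1] = i
    labels = view_labels.labels
    n_lab = int(labels.max()) + 1
    final = np.empty(n, dtype=int)
    for i in range(n):
        own = labels[:, i]
        if (own == own[0]).all():
            # the neighbourhood vote only arbitrates cross-view disagreement;
            # a sample all views agree on keeps its label
            final[i] = own[0]
            continue
        votes = labels[:, idx[i]].ravel()
        counts = np.bincount(votes, minlength=n_lab)
        top = np.flatnonzero(counts == counts.max())
        if len(top) > 1:
            own = np.bincount(labels[:, i], minlength=n_lab)
            own_top = top[own[top] == own[top].max()]
            top = own_top if len(own_top) else top
        final[i] = top.min()
    return IntegratedClustering(
        final_labels=final,
        per_view=view_labels,
        K=n_lab,
    )
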