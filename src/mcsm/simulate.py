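"""Multi-view stochastic-block-model simulator.

Generates M binary undirected networks over the same N nodes.  Every view
draws its edges independently from a shared K × K connection-probability
matrix, but assigns the nodes to clusters according to its own cluster-size
vector, so the planted partitions differ between views (only "core" nodes
keep their cluster across views; boundary nodes switch).  This emulates
multi-omics cohorts in which data types disagree about subtype membership.

The built-in probability matrices P1–P4 and the two study settings follow
the simulation protocol the package is evaluated against: within-cluster
probabilities around 16–18/N against between-cluster probabilities from 0
(P1, perfectly separable) up to 1.8/N (P4).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "P_MATRICES",
    "SETTINGS",
    "SBMSpec",
    "SimulatedMultiView",
    "assign_clusters",
    "sample_network",
    "simulate_multiview",
]

# printed as multiples of 1/N; scaled by the setting's node count in SBMSpec
P_MATRICES = {
    1: np.array([[16.0, 0.0, 0.0], [0.0, 18.0, 0.0], [0.0, 0.0, 17.0]]),
    2: np.array([[16.0, 0.4, 0.6], [0.4, 18.0, 0.55], [0.6, 0.55, 17.0]]),
    3: np.array([[16.0, 0.8, 1.2], [0.8, 18.0, 1.1], [1.2, 1.1, 17.0]]),
    4: np.array([[16.0, 1.2, 1.8], [1.2, 18.0, 1.65], [1.8, 1.65, 17.0]]),
}

SETTINGS = {
    1: {
        "M": 3,
        "N": 150,
        "distributions": [(50, 50, 50), (30, 90, 30), (40, 60, 50)],
    },
    2: {
        "M": 6,
        "N": 1000,
        "distributions": [
            (300, 300, 400),
            (300, 300, 400),
            (400, 300, 300),
            (300, 350, 350),
            (300, 400, 300),
            (450, 250, 300),
        ],
    },
}


@dataclass
class SBMSpec:
    """Connection probabilities plus per-view cluster sizes for one study.

    ``P`` holds final probabilities (already divided by N); each of the M
    ``distributions`` is a K-vector of cluster sizes summing to N.
    """

    P: np.ndarray
    distributions: list[tuple[int, ...]]
    N: int
    seed: int = 0

    def __post_init__(self) -> None:
        self.P = np.asarray(self.P, dtype=float)
        if self.P.ndim != 2 or self.P.shape[0] != self.P.shape[1]:
            raise ValueError("P must be square")
        if not np.allclose(self.P, self.P.T):
            raise ValueError("P must be symmetric")
        if self.P.min() < 0 or self.P.max() > 1:
            raise ValueError("P entries must be probabilities in [0, 1]")
        k = self.P.shape[0]
        for dist in self.distributions:
            if len(dist) != k:
                raise ValueError("each distribution must have K entries")
            if sum(dist) != self.N:
                raise ValueError(f"cluster sizes {dist} do not sum to N={self.N}")

    @property
    def M(self) -> int:
        return len(self.distributions)

    @property
    def K(self) -> int:
        return self.P.shape[0]

    @classmethod
    def from_setting(cls, setting: int, pmatrix: int, seed: int = 0) -> "SBMSpec":
        """Build a spec from the canonical study settings (1 or 2, P1–P4)."""
        cfg = SETTINGS[setting]
        return cls(
            P=P_MATRICES[pmatrix] / cfg["N"],
            distributions=list(cfg["distributions"]),
            N=cfg["N"],
            seed=seed,
        )

    def with_seed(self, seed: int) -> "SBMSpec":
        return replace(self, seed=seed)


@dataclass
class SimulatedMultiView:
    """M binary symmetric adjacency matrices with per-view planted labels."""

    adjacencies: list[np.ndarray]
    truth: np.ndarray  # M × N planted labels

    @property
    def M(self) -> int:
        return len(self.adjacencies)

    @property
    def N(self) -> int:
        return self.adjacencies[0].shape[0]


def assign_clusters(distribution, N: int) -> np.ndarray:
    """Deterministic contiguous assignment: first n1 nodes → cluster 0, etc.

    Keeping blocks contiguous preserves cluster identity for core nodes
    across views with different size vectors; only boundary nodes switch.
    """
    if sum(distribution) != N:
        raise ValueError(f"cluster sizes {tuple(distribution)} do not sum to N={N}")
    return np.repeat(np.arange(len(distribution)), distribution)


def sample_network(labels: np.ndarray, P: np.ndarray, seed: int) -> np.ndarray:
    """Draw a binary symmetric adjacency with Bernoulli(P[c_i, c_j]) edges."""
    P = np.asarray(P, dtype=float)
    if P.min() < 0 or P.max() > 1:
        raise ValueError("P entries must be probabilities in [0, 1]")
    labels = np.asarray(labels)
    n = labels.size
    rng = np.random.default_rng(seed)
    prob = P[labels][:, labels]
    upper = np.triu(rng.random((n, n)) < prob, k=1)
    A = (upper | upper.T).astype(np.int8)
    return A


def simulate_multiview(spec: SBMSpec) -> SimulatedMultiView:
    """Generate M independent networks with per-view planted labels.

    Each view uses seed = spec.seed + view index so views are independent
    yet the full output is reproducible bit-for-bit from the spec.
    """
    truth = np.vstack([assign_clusters(d, spec.N) for d in spec.distributions])
    adjacencies = [
        sample_network(truth[m], spec.P, seed=(spec.seed + m) % (2**31))
        for m in range(spec.M)
    ]
    return SimulatedMultiView(adjacencies=adjacencies, truth=truth)
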