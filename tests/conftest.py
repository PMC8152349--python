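import numpy as np
import pytest

from mcsm.graph import ViewGraph, joint_laplacian
from mcsm.preprocess import OmicsMatrix
from mcsm.simulate import SBMSpec, simulate_multiview


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)


@pytest.fixture
def small_omics(rng):
    """6 features × 8 samples complete matrix with mild structure."""
    values = rng.standard_normal((6, 8)) + np.arange(8) * 0.3
    return OmicsMatrix(values)


@pytest.fixture
def sbm30():
    """30-node, 3-block planted partition with strong separation."""
    spec = SBMSpec(
        P=np.array([[0.8, 0.05, 0.05], [0.05, 0.8, 0.05], [0.05, 0.05, 0.8]]),
        distributions=[(10, 10, 10)],
        N=30,
        seed=5,
    )
    return simulate_multiview(spec)


@pytest.fixture
def sbm30_multi():
    """Three views over 30 nodes with differing planted partitions."""
    spec = SBMSpec(
        P=np.array([[0.8, 0.05, 0.05], [0.05, 0.8, 0.05], [0.05, 0.05, 0.8]]),
        distributions=[(10, 10, 10), (8, 14, 8), (12, 10, 8)],
        N=30,
        seed=11,
    )
    return simulate_multiview(spec)


@pytest.fixture
def joint_sbm30(sbm30_multi):
    views = [ViewGraph.from_adjacency(a) for a in sbm30_multi.adjacencies]
    return joint_laplacian(views, beta=1.0)


def random_orthonormal(rng, n, k):
    q, _ = np.linalg.qr(rng.standard_normal((n, k)))
    return q
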