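import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from nichemap import DiffusionMap
from nichemap.synthetic import ClusterSpec, make_clustered_traits


@pytest.fixture(scope="session")
def two_cluster_fixture():
    """Two planted 5-genome clusters plus background, light bit-flip noise.

    Cluster sizes are kept below the smallest k used in robustness checks
    so the union-kNN graph stays connected.
    """
    spec = ClusterSpec(
        n_core_traits=40,
        clusters=[(5, 20), (5, 20)],
        n_background_genomes=15,
        flip_prob=0.02,
        seed=0,
        force_unique=True,
    )
    return make_clustered_traits(spec)


@pytest.fixture(scope="session")
def three_cluster_map():
    """60-genome, 3-cluster fixture with a fitted 50-variable diffusion map.

    Large enough to carry 50 diffusion variables (the configuration used
    for niche fingerprints) and shared across enrichment/community tests.
    """
    spec = ClusterSpec(
        n_core_traits=60,
        clusters=[(5, 25), (5, 25), (5, 25)],
        n_background_genomes=45,
        flip_prob=0.02,
        seed=3,
        force_unique=True,
    )
    T, labels = make_clustered_traits(spec)
    dm = DiffusionMap(k=10, n_variables=50).fit(T)
    return T, labels, dm


@pytest.fixture()
def path3_graph():
    """Unit-weight 3-node path graph g1-g2-g3."""
    from nichemap.diffusion import NeighborGraph

    W = np.array([[0.0, 1, 0], [1, 0, 1], [0, 1, 0]])
    return NeighborGraph(["g1", "g2", "g3"], W)
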