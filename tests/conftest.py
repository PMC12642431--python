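import numpy as np
import pytest

from psn_atlas.cluster import ClusterParams, iterate_clustering
from psn_atlas.qc import apply_qc
from psn_atlas.sim.atlas import default_atlas_config, simulate_atlas


@pytest.fixture(scope="session")
def default_atlas():
    """Default synthetic atlas, seed 0 (136 cells before QC)."""
    return simulate_atlas(default_atlas_config(seed=0))


@pytest.fixture(scope="session")
def kept_atlas(default_atlas):
    """QC-passing cells of the default atlas (123 neurons)."""
    kept, _ = apply_qc(default_atlas)
    return kept


@pytest.fixture(scope="session")
def atlas_tree(kept_atlas):
    """Cluster tree of the default atlas at seed 0."""
    return iterate_clustering(kept_atlas, ClusterParams(seed=0))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
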