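import numpy as np
import pytest

from topolearn import FeatureMatrix, SyntheticSpec, make_landscape, make_point_cloud


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def unit_square():
    return FeatureMatrix(np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0], [1.0, 1.0]]))


@pytest.fixture
def small_cloud(rng):
    return FeatureMatrix(rng.random((30, 3)))


@pytest.fixture
def smooth_landscape():
    cloud = make_point_cloud(SyntheticSpec(shape="hypercube", n=150, dim=2, seed=7))
    return make_landscape(cloud, cliff_fraction=0.0, seed=7)


@pytest.fixture
def cliff_landscape():
    cloud = make_point_cloud(SyntheticSpec(shape="hypercube", n=150, dim=2, seed=7))
    return make_landscape(cloud, cliff_fraction=0.5, seed=7)
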