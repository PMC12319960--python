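import numpy as np
import pytest

from chisep.acquisition import AcquisitionParams
from chisep.phantom import make_phantom


@pytest.fixture(scope="session")
def params():
    """Default 8-echo protocol (TE1 = 4 ms, spacing 3.8 ms, 11.7 T)."""
    return AcquisitionParams.default()


@pytest.fixture(scope="session")
def params_unit_voxel():
    return AcquisitionParams.default(voxel_size=(1.0, 1.0, 1.0))


@pytest.fixture(scope="session")
def shells_truth():
    return make_phantom(32, layout="shells", seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
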