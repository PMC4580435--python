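import numpy as np
import pytest

from tvpet import (
    brain_like_spec,
    default_geometry,
    disc_spec,
    forward_project,
    make_phantom,
)


@pytest.fixture(scope="session")
def brain_truth():
    return make_phantom(brain_like_spec(64))


@pytest.fixture(scope="session")
def brain_geometry():
    return default_geometry(64, n_s=64, n_phi=96)


@pytest.fixture(scope="session")
def brain_sino(brain_truth, brain_geometry):
    """Noiseless sinogram of the 64x64 brain-like phantom."""
    return forward_project(brain_truth, brain_geometry)


@pytest.fixture(scope="session")
def disk_truth():
    return make_phantom(disc_spec(64))


@pytest.fixture(scope="session")
def disk_sino(disk_truth):
    g = default_geometry(64, n_s=64, n_phi=96)
    return forward_project(disk_truth, g)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
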