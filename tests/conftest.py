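import numpy as np
import pytest

from volscape.synthetic import default_masks, default_phantom_spec, render_phantom


@pytest.fixture(scope="session")
def spec48():
    """Default phantom at production scale (box 48, 4 A voxels)."""
    return default_phantom_spec(box=48, voxel_size=4.0, seed=0)


@pytest.fixture(scope="session")
def spec32():
    """Same physical phantom on a coarser lattice; cheap for heavy loops."""
    return default_phantom_spec(box=32, voxel_size=6.0, seed=0)


@pytest.fixture(scope="session")
def ref48(spec48):
    return render_phantom(spec48, 0.0)


@pytest.fixture(scope="session")
def refs_two_state_32(spec32):
    return render_phantom(spec32, 25.0), render_phantom(spec32, 0.0)


@pytest.fixture(scope="session")
def masks48(spec48):
    return default_masks(spec48)


@pytest.fixture(scope="session")
def masks32(spec32):
    return default_masks(spec32)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
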