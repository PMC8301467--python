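import numpy as np
import pytest

from mandmorph import imagecore, phantom


@pytest.fixture(scope="session")
def rat02():
    """Coarse noise-free rat phantom (0.2 mm voxels) shared across tests."""
    return phantom.make_phantom(phantom.rat_spec(voxel_mm=0.2))


@pytest.fixture(scope="session")
def rat01():
    return phantom.make_phantom(phantom.rat_spec(voxel_mm=0.1))


@pytest.fixture(scope="session")
def rabbit01():
    return phantom.make_phantom(phantom.rabbit_spec(voxel_mm=0.1))


@pytest.fixture
def masks():
    """Helper splitting a phantom volume into (bone, tooth) masks."""
    return imagecore.split_bone_teeth


@pytest.fixture
def bone_block():
    """Uniform 12 mm cube of bone at 0.1 mm voxels (for defect oracles)."""
    n = 120
    data = np.full((n, n, n), phantom.BONE_INTENSITY, dtype=np.float32)
    vol = imagecore.Volume(data, (0.1, 0.1, 0.1), (-6.0, -6.0, -6.0))
    mask = imagecore.Volume(np.ones((n, n, n), dtype=np.uint8), vol.spacing, vol.origin)
    return vol, mask
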