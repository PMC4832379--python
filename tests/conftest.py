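import numpy as np
import pytest

from physis import PhantomSpec, make_plate_phantom


@pytest.fixture(scope="session")
def default_phantom():
    """Reference phantom with 5 planted bridges and its ground truth."""
    return make_plate_phantom(PhantomSpec(seed=42))


@pytest.fixture(scope="session")
def noise_free_phantom():
    return make_plate_phantom(PhantomSpec(seed=42, noise_sigma=0.0))


@pytest.fixture
def two_slabs():
    """Two full-width slabs separated by a 10-voxel gap (spacing 1 μm)."""
    from physis import BinaryMask

    m = np.zeros((40, 30, 30), bool)
    m[5:15] = True
    m[25:35] = True
    return BinaryMask(m, 1.0)
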