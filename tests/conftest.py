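import numpy as np
import pytest

from fibrilscope.phantoms import PhantomSpec, make_microfibril_phantom


@pytest.fixture(scope="session")
def default_phantom():
    """Default beaded-repeat phantom on a 96-px box at 8 A/voxel."""
    return make_microfibril_phantom(PhantomSpec(), 96, 8.0)


@pytest.fixture(scope="session")
def phantom_c8():
    """Phantom with eight-fold axial symmetry (8 interbead strands)."""
    return make_microfibril_phantom(PhantomSpec(axial_symmetry_order=8), 96, 8.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def smooth_test_image(rng, shape=(48, 48), sigma=2.0):
    from scipy import ndimage
    return ndimage.gaussian_filter(rng.normal(size=shape), sigma)
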