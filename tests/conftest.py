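import numpy as np
import pytest

from vhucsnet.phantom import PhantomSpec, generate_arrays


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_spec():
    """32x32 phantoms: the smallest size both networks accept with the
    desk presets (divisible by patch*2^3 and by 2^3)."""
    return PhantomSpec(image_size=(32, 32),
                       organ_axes_range=((7.0, 11.0), (6.0, 9.0)),
                       mass_radius_range=(2.5, 4.5), seed=7)


@pytest.fixture(scope="session")
def tiny_pairs(tiny_spec):
    return generate_arrays(24, tiny_spec)


def random_mask(rng, shape, p=0.5):
    return (rng.random(shape) < p).astype(np.uint8)
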