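import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")

from pyranoid.synthetic_fixtures import make_sugar
from pyranoid.torsion_patcher import patch_dictionary
from pyranoid.validation import load_expectations


@pytest.fixture(scope="session")
def nag():
    """Idealized beta-D-GlcNAc-like sugar in the 4C1 chair."""
    return make_sugar("D", "4C1", "beta", "NAG")


@pytest.fixture(scope="session")
def nag_patched(nag):
    coords, d = nag
    return patch_dictionary(d, coords)


@pytest.fixture(scope="session")
def expectations():
    return load_expectations()


@pytest.fixture()
def rng():
    return np.random.default_rng(4117)


def random_rotation(rng):
    """Uniform random proper rotation matrix."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )
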