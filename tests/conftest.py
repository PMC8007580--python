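import numpy as np
import pytest
from hypothesis import settings

from ordivox.phantom import PhantomConfig, phantom_dataset

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")

#: small phantom used by unit tests (fast; 1,680 voxels, 38 images)
TINY_PHANTOM = PhantomConfig(
    dims=(12, 14, 10),
    class_counts=(16, 12, 10),
    centers=((5.5, 4.0, 4.5), (5.5, 9.0, 4.5)),
    semi_axes=(2.0, 1.5, 2.5),
)


@pytest.fixture(scope="session")
def tiny_phantom():
    """(dataset, signal feature indices) of the small phantom, seed 123."""
    return phantom_dataset(TINY_PHANTOM, seed=123)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
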