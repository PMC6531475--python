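import numpy as np
import pytest

from msmdenoise import PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def small_phantom():
    """A 128x128 clustered-cell phantom shared by the slower tests."""
    spec = PhantomSpec(
        height=128, width=128, n_cells=8, n_clusters=3,
        cell_radius_range=(10.0, 16.0), seed=1,
    )
    return generate_phantom(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
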