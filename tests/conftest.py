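import numpy as np
import pytest

from renogray import PhantomSpec, default_ranges


@pytest.fixture(scope="session")
def ranges14():
    return default_ranges()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_spec():
    """A small phantom raster; group statistics only see per-image GSMs,
    so the raster size does not matter for statistical checks."""
    return PhantomSpec(width=160, height=120, seed=5)


@pytest.fixture(scope="session")
def medium_spec():
    return PhantomSpec(width=400, height=300, seed=7)
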