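import numpy as np
import pytest

from hdikit.grid import DEFAULT_LEGEND, GridSpec, LandUseGrid, ValueGrid


@pytest.fixture
def spec():
    return GridSpec(10, 10, 1000.0, 0.0, 10_000.0, "test-meters")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_landuse(spec, rng):
    """Random mosaic covering all nine classes (codes 1..9)."""
    codes = rng.integers(1, 10, size=spec.shape)
    return LandUseGrid(spec, codes, DEFAULT_LEGEND)


@pytest.fixture
def random_values(spec, rng):
    return ValueGrid(spec, rng.random(spec.shape) * 100.0, units="quantity/km2")
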