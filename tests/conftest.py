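import numpy as np
import pytest

from weedspec.hsi_core import HSICube, WavelengthGrid


@pytest.fixture
def grid10() -> WavelengthGrid:
    """10 evenly spaced band centers 400..1000 nm."""
    return WavelengthGrid(np.linspace(400.0, 1000.0, 10))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(42)


@pytest.fixture
def small_cube(grid10, rng) -> HSICube:
    """A 6x5 random reflectance cube on the 10-band grid."""
    return HSICube(values=rng.uniform(0.05, 0.9, size=(6, 5, 10)), grid=grid10)
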