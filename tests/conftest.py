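import numpy as np
import pytest

from holoshear import OpticalConfig


@pytest.fixture(scope="session")
def small_optics() -> OpticalConfig:
    """Reduced sensor at the instrument's pixel pitch; full 4 cm path, 70 planes."""
    return OpticalConfig(sensor_px=(256, 256))


@pytest.fixture(scope="session")
def mid_optics() -> OpticalConfig:
    """512 px sensor used for imaging round trips (2.35 mm field of view)."""
    return OpticalConfig(sensor_px=(512, 512))


def make_mask(shape, painter):
    """Boolean canvas helper for constructing test regions."""
    mask = np.zeros(shape, dtype=bool)
    painter(mask)
    return mask
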