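import numpy as np
import pytest

from fpmnet import (
    ComplexField,
    OpticsGeometry,
    bandlimit_field,
    channels_to_complex,
    generate_hr_pair,
)


@pytest.fixture(scope="session")
def small_geometry() -> OpticsGeometry:
    """5x5 LEDs on a 32-pixel HR grid: small enough for brute-force oracles."""
    return OpticsGeometry(hr_size=32, downsample_factor=2, led_grid=5)


@pytest.fixture(scope="session")
def default_geometry_64() -> OpticsGeometry:
    """The full 13x13 LED array on a 64-pixel HR grid."""
    return OpticsGeometry(hr_size=64)


def make_object(geometry: OpticsGeometry, seed: int, style: str = "blobs",
                band_limited: bool = True) -> ComplexField:
    """Procedural complex test object, optionally projected onto the
    synthetic-aperture passband so it is fully recoverable."""
    hr = generate_hr_pair(geometry.hr_size, seed, style)
    obj = channels_to_complex(hr, pixel_size=geometry.hr_pixel)
    return bandlimit_field(obj, geometry) if band_limited else obj


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
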