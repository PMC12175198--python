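import numpy as np
import pytest

from fpmkit import OpticalConfig, reference_config, simulate_stack
from fpmkit.phantoms import PhantomSpec, make_phantom


@pytest.fixture(scope="session")
def tiny_config():
    """3×3 LEDs, 8×8 captures, 16×16 object grid — oracle-sized."""
    return OpticalConfig(wavelength=0.523, objective_na=0.3, magnification=10.0,
                         camera_pixel=6.5, led_grid=(3, 3), led_pitch=4.0,
                         led_height=52.0, hr_upsample=2, lr_shape=(8, 8))


@pytest.fixture(scope="session")
def small_config():
    """5×5 LEDs, 16×16 captures — fast end-to-end runs."""
    return OpticalConfig(wavelength=0.523, objective_na=0.3, magnification=10.0,
                         camera_pixel=6.5, led_grid=(5, 5), led_pitch=4.0,
                         led_height=52.0, hr_upsample=2, lr_shape=(16, 16))


@pytest.fixture(scope="session")
def tiny_phantom(tiny_config):
    return make_phantom(PhantomSpec(kind="tissue", size=tiny_config.hr_side,
                                    pixel_size=tiny_config.hr_pixel,
                                    feature_scale=1.5, band_limit=1.5, seed=3))


@pytest.fixture(scope="session")
def small_phantom(small_config):
    return make_phantom(PhantomSpec(kind="tissue", size=small_config.hr_side,
                                    pixel_size=small_config.hr_pixel,
                                    feature_scale=1.5, band_limit=1.5, seed=3))


@pytest.fixture(scope="session")
def small_stack(small_phantom, small_config):
    return simulate_stack(small_phantom, small_config, z=0.0)
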