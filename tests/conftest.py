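import numpy as np
import pytest

import holotomo as ht
from holotomo.forward import simulate_stack


@pytest.fixture(scope="session")
def cfg64():
    """Small-volume configuration with the default (561 nm, NA 1.0/1.45) optics."""
    return ht.OpticsConfig(detector_shape=(64, 64), volume_shape=(64, 64, 32))


@pytest.fixture(scope="session")
def dq64(cfg64):
    """Detector frequency-bin width (rad/nm)."""
    return 2 * np.pi / (cfg64.detector_shape[0] * cfg64.pixel_size)


@pytest.fixture(scope="session")
def sphere_phantom(cfg64):
    spec = ht.PhantomSpec.of(
        ht.Primitive("sphere", (0.0, 0.0, 0.0), ri=1.347, radius=600.0))
    return ht.build_phantom(spec, cfg64)


@pytest.fixture(scope="session")
def sphere_potential(cfg64, sphere_phantom):
    return ht.scattering_potential(sphere_phantom, cfg64)


@pytest.fixture(scope="session")
def sphere_stack(cfg64, sphere_phantom):
    """Noiseless 20-angle ring stack of the centered weak sphere."""
    scan = ht.generate_scan_pattern(cfg64, 20)
    stack, truth = simulate_stack(sphere_phantom, scan, None, None, cfg64)
    return stack, truth
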