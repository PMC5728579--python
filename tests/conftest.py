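import dataclasses

import numpy as np
import pytest

import specresolve as sr
from specresolve.phantom import default_phantom_config, generate_phantom


@pytest.fixture
def printed_gradient():
    """17-entry gradient of a peak followed by a positive slope."""
    return np.array(
        [1, 2, 4, 6, 8, 6, 2, -4, -6, -8, -7, -3, -1, 3, 6, 8, 10], dtype=float
    )


@pytest.fixture
def fine17_cal():
    """First 17 channels of the full-resolution default calibration, so
    adjacent channels are ~0.2 nm apart as on the real detector."""
    return sr.WavelengthCalibration(sr.default_calibration(1340).wavelength_nm[:17])


@pytest.fixture(scope="session")
def noiseless_phantom():
    """Deterministic noise-free, cosmic-free benchmark phantom + truth."""
    cfg = dataclasses.replace(
        default_phantom_config(seed=1, noise="none"), cosmic_ray_rate=0.0
    )
    cube, truth = generate_phantom(cfg)
    return cfg, cube, truth


@pytest.fixture(scope="session")
def noiseless_resolved(noiseless_phantom):
    _, cube, _ = noiseless_phantom
    return sr.resolve_cube(cube, sr.MethodIIParams(), method=2)
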