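import numpy as np
import pytest

from catphanqa.detection import detect_landmarks
from catphanqa.simulate import SimulationConfig, render_scan

# Standard test protocol: mid-range pixel size, 3 mm slices, moderate blur
# and noise, comparable to a smooth-kernel clinical CT reconstruction.
STD_KWARGS = dict(matrix_size=384, pixel_size=0.6, slice_thickness=3.0,
                  psf_sigma=0.6, noise_sigma=8.0, rng_seed=11)

# Degradation-free render for exactness checks.
CLEAN_KWARGS = dict(matrix_size=384, pixel_size=0.6, slice_thickness=3.0,
                    psf_sigma=0.0, noise_sigma=0.0, rng_seed=1)

# Coarse, fast render for tests that only need plausible structure.
FAST_KWARGS = dict(matrix_size=256, pixel_size=0.9, slice_thickness=3.0,
                   psf_sigma=0.6, noise_sigma=5.0, rng_seed=3)


@pytest.fixture(scope="session")
def std_scan():
    return render_scan(SimulationConfig(**STD_KWARGS))


@pytest.fixture(scope="session")
def std_landmarks(std_scan):
    volume, _ = std_scan
    return detect_landmarks(volume)


@pytest.fixture(scope="session")
def clean_scan():
    return render_scan(SimulationConfig(**CLEAN_KWARGS))


@pytest.fixture(scope="session")
def clean_landmarks(clean_scan):
    volume, _ = clean_scan
    return detect_landmarks(volume)


@pytest.fixture(scope="session")
def fast_scan():
    return render_scan(SimulationConfig(**FAST_KWARGS))
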