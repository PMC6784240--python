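import numpy as np
import pytest

from dopplertrace import AxisCalibration, GrayImage, RegionOfInterest, SynthSpec, generate


@pytest.fixture
def cal() -> AxisCalibration:
    return AxisCalibration(velocity_per_pixel=0.34, time_per_pixel=1.9)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


@pytest.fixture
def small_roi() -> RegionOfInterest:
    return RegionOfInterest(n_up=2, n_lo=61, y_base=32)


@pytest.fixture
def clean_spectrogram(cal):
    """Hard-edged, noise-free synthetic spectrogram with ground truth."""
    spec = SynthSpec(noise_sd=0.0, speckle_density=0.0, decay=0.0, seed=0)
    return generate(spec, cal)


@pytest.fixture
def noisy_spectrogram(cal):
    """Default-condition synthetic spectrogram (moderate noise + speckle)."""
    return generate(SynthSpec(seed=7), cal)


def make_gray(arr) -> GrayImage:
    return GrayImage(np.asarray(arr, dtype=float))
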