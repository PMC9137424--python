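import numpy as np
import pytest

from maskedspeech.acoustics import Waveform, estimate_magnitude_spectrum
from maskedspeech.synthetic import synth_attenuation_profile, synth_face_landmarks


@pytest.fixture(scope="session")
def white_noise_60s():
    rng = np.random.default_rng(12345)
    return Waveform(rng.standard_normal(60 * 44100) * 0.05, 44100)


@pytest.fixture(scope="session")
def white_noise_spectrum(white_noise_60s):
    return estimate_magnitude_spectrum(white_noise_60s)


@pytest.fixture(scope="session")
def fabric_profile():
    return synth_attenuation_profile("fabric-like")


@pytest.fixture(scope="session")
def landmark_frames():
    return synth_face_landmarks(8, aperture_px=10.0, seed=42)
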