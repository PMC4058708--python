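import numpy as np
import pytest

from eegsmallworld.montage import CHANNELS_1020
from eegsmallworld.synthetic import OscillatorSpec, PatternSpec, generate_epoch


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_tone_epoch(freq=10.0, amplitude=30.0, channels=("Fp1", "Fp2"),
                    noise_sd=0.0, duration=20.0, seed=0, archetype="normal"):
    """Small noise-free (by default) epoch with one planted oscillator."""
    spec = PatternSpec(
        archetype,
        (OscillatorSpec(freq, amplitude, 0.3, tuple(channels)),),
        noise_sd=noise_sd,
        duration=duration,
        seed=seed,
    )
    return generate_epoch(spec)


@pytest.fixture
def all_channels():
    return CHANNELS_1020
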