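import numpy as np
import pytest

from surrseg import CohortSpec, SynthConfig, generate_linear_cyclic
from surrseg.recording import MultichannelRecording


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def sine_recording():
    """Pure 10 Hz sine at 1000 Hz, 10 s, single channel."""
    t = np.arange(10_000) / 1000.0
    return MultichannelRecording(
        samples=np.sin(2 * np.pi * 10.0 * t),
        sampling_rate_hz=1000.0,
        channel_labels=["O1"],
    )


@pytest.fixture(scope="session")
def cyclic_recording():
    """Synthetic cyclic recording: 10 Hz at half power over 1/f noise, 200 Hz."""
    config = SynthConfig(
        duration_s=60.0,
        sampling_rate_hz=200.0,
        alpha_freq_hz=10.0,
        alpha_rel_power=0.5,
        noise_exponent=1.0,
        channel_labels=["O1"],
        seed=99,
    )
    return generate_linear_cyclic(config)


@pytest.fixture(scope="session")
def small_cohort():
    return CohortSpec(
        n_subjects=3,
        n_segments_per_subject=6,
        seed=11,
        sampling_rate_hz=200.0,
        alpha_rel_power=0.5,
    )
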