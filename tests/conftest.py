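import numpy as np
import pytest

from lassa.synth import PulseSimConfig, simulate_pulse_trace


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def clean_72bpm_trace():
    """Noiseless 60 s pulse at 72 bpm, 30 fps."""
    cfg = PulseSimConfig(
        duration_s=60.0, fps=30.0, hr_bpm=72.0,
        drift_amplitude=0.0, noise_sigma=0.0, artifact_rate=0.0, seed=1,
    )
    return simulate_pulse_trace(cfg)
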