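import numpy as np
import pytest

from spkrecon.dsp import NormalizedPair
from spkrecon.synthio import SynthConfig, TemplateParams, generate_recording


@pytest.fixture(scope="session")
def short_recording():
    """4-channel, 10 s recording with one -120 μV unit per channel."""
    cfg = SynthConfig(n_channels=4, duration=10.0, units_per_channel=1,
                      template_params=[TemplateParams(-120.0, 1.0, 0.3)],
                      seed=42)
    return generate_recording(cfg)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


def make_pair(hpf, lpf=None, fs=25_000.0, electrode_id=0):
    """NormalizedPair stub for training tests (already 'normalized')."""
    hpf = np.asarray(hpf, dtype=float)
    lpf = np.zeros_like(hpf) if lpf is None else np.asarray(lpf, dtype=float)
    return NormalizedPair(lpf, hpf, 1.0, fs, electrode_id)
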