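import numpy as np
import pytest

from eitqct.eit_signal import ImpedanceSeries
from eitqct.synthetic_data import BreathWaveformSpec, generate_breath_waveform


@pytest.fixture
def clean_spec():
    """Noiseless, cardiac-free, drift-free breathing at 12 cpm."""
    return BreathWaveformSpec(duration_s=90.0, respiratory_rate_cpm=12.0,
                              cardiac_amplitude_fraction=0.0, noise_sd=0.0,
                              baseline_drift_amplitude=0.0, ei_ratio_target=2.0)


@pytest.fixture
def composite_spec():
    """12 cpm breathing plus 70 cpm cardiac at 10% of tidal amplitude."""
    return BreathWaveformSpec(duration_s=60.0, respiratory_rate_cpm=12.0,
                              cardiac_rate_cpm=70.0, cardiac_amplitude_fraction=0.10,
                              noise_sd=0.0, baseline_drift_amplitude=0.0)


def make_tone(freq_cpm, duration_s=60.0, sample_rate_hz=10.0, amplitude=1.0, phase=0.0):
    t = np.arange(int(round(duration_s * sample_rate_hz))) / sample_rate_hz
    return ImpedanceSeries(values=amplitude * np.sin(2 * np.pi * freq_cpm / 60.0 * t + phase),
                           sample_rate_hz=sample_rate_hz)


@pytest.fixture
def tone_factory():
    return make_tone
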