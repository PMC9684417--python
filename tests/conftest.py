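import numpy as np
import pytest

from fecg_sagwo.io_formats import SignalRecord
from fecg_sagwo.synthetic_data import SynthConfig, generate_record


@pytest.fixture(scope="session")
def default_record():
    """A 60 s default-condition abdominal record with ground truth."""
    return generate_record(SynthConfig(duration_s=60.0, seed=7))


@pytest.fixture(scope="session")
def clean_maternal():
    """Noise-free maternal-only record (baseline/mains/noise off)."""
    cfg = SynthConfig(duration_s=60.0, seed=11, fetal_amplitude_ratio=0.0,
                      baseline_amp=0.0, mains_amp=0.0, snr_db=None,
                      noise_rms=None)
    return generate_record(cfg)


def sine_record(freq_hz: float, fs: float = 500.0, duration_s: float = 10.0,
                amplitude: float = 1.0, n_channels: int = 1) -> SignalRecord:
    t = np.arange(int(duration_s * fs)) / fs
    wave = amplitude * np.sin(2 * np.pi * freq_hz * t)
    return SignalRecord(np.tile(wave, (n_channels, 1)), fs)
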