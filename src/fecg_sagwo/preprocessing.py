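"""Baseline-wander and powerline-interference removal.

Abdominal ECG channels carry a slow baseline drift (respiration,
electrode motion, < 1 Hz) and narrowband mains interference (50 or
60 Hz).  Both are removed per channel with zero-phase IIR filters so
that R-peak timing is untouched:

* high-pass: Butterworth, default order 4 at 1.0 Hz (preserves P/T
  morphology while removing drift), applied forward-backward;
* notch: second-order IIR notch at the mains frequency, default
  Q = 30, also forward-backward.

The cutoffs are this package's choice of standard ECG practice; they
are configurable through :class:`PreprocessConfig`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .io_formats import SignalRecord

__all__ = ["PreprocessConfig", "remove_baseline", "remove_powerline", "preprocess"]


@dataclass(frozen=True)
class PreprocessConfig:
    """Filter settings for the pre-processing stage."""

    highpass_cutoff_hz: float = 1.0
    highpass_order: int = 4
    notch_freq_hz: float = 50.0
    notch_q: float = 30.0

    def __post_init__(self) -> None:
        if self.highpass_cutoff_hz <= 0:
            raise ValueError("highpass cutoff must be positive")
        if self.highpass_order < 1:
            raise ValueError("highpass order must be >= 1")
        if self.notch_freq_hz <= self.highpass_cutoff_hz:
            raise ValueError("notch frequency must exceed the high-pass cutoff")
        if self.notch_q <= 0:
            raise ValueError("notch Q must be positive")


def _check_nyquist(freq_hz: float, fs: float, what: str) -> None:
    if freq_hz >= fs / 2:
        raise ValueError(
            f"{what} {freq_hz} Hz is not below the Nyquist rate {fs / 2} Hz"
        )


def highpass_sos(cfg: PreprocessConfig, fs: float) -> np.ndarray:
    """Second-order sections of the baseline high-pass at rate ``fs``."""
    _check_nyquist(cfg.highpass_cutoff_hz, fs, "high-pass cutoff")
    return sps.butter(cfg.highpass_order, cfg.highpass_cutoff_hz,
                      btype="highpass", fs=fs, output="sos")


def notch_ba(cfg: PreprocessConfig, fs: float) -> tuple[np.ndarray, np.ndarray]:
    """(b, a) of the mains notch at rate ``fs``."""
    _check_nyquist(cfg.notch_freq_hz, fs, "notch frequency")
    return sps.iirnotch(cfg.notch_freq_hz, cfg.notch_q, fs=fs)


def remove_baseline(record: SignalRecord,
                    cfg: PreprocessConfig = PreprocessConfig()) -> SignalRecord:
    """Zero-phase high-pass each channel; shape, fs and labels unchanged."""
    sos = highpass_sos(cfg, record.fs)
    filtered = sps.sosfiltfilt(sos, record.samples, axis=1)
    return record.with_samples(filtered)


def remove_powerline(record: SignalRecord,
                     cfg: PreprocessConfig = PreprocessConfig()) -> SignalRecord:
    """Zero-phase mains notch on each channel."""
    b, a = notch_ba(cfg, record.fs)
    filtered = sps.filtfilt(b, a, record.samples, axis=1)
    return record.with_samples(filtered)


def preprocess(record: SignalRecord,
               cfg: PreprocessConfig = PreprocessConfig()) -> SignalRecord:
    """Baseline removal followed by mains-notch removal (deterministic)."""
    return remove_powerline(remove_baseline(record, cfg), cfg)
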