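"""Synthetic abdominal-ECG generator with full ground truth.

Each cardiac source is a train of sum-of-Gaussians beats (P, Q, R, S, T
waves) placed at jittered RR intervals.  The maternal beat occupies
exactly the 0.70 s analysis window used by the sequential-analysis
template model ([-0.25 s, +0.45 s) around the R-peak), and its P, QRS
and T sections are multiplied per cycle by independently drawn scaling
factors — the time-varying morphology that per-beat template scaling is
built to track.  Because the scaling multiplies the *windowed section
samples* of a fixed prototype, the generated cycle is exactly a
block-scaled copy of the prototype sections, which makes exact
closed-form recovery of the drawn scalings possible on the clean
source.

Channels are a linear mixture of the maternal and the lower-amplitude,
higher-rate fetal source, plus sinusoidal baseline wander, mains
interference and white noise.  The white-noise level can be given
directly (``noise_rms``) or via a signal-to-noise ratio in dB relative
to the clean mixed signal (``snr_db``, the default, 20 dB).

What this emulates — and what it does not: per-cycle amplitude
modulation, rate jitter, additive stationary noise and fixed linear
mixing.  Real abdominal records add electrode motion artifacts,
uterine EMG, fetal position changes and non-stationary mixing; results
on this generator bound what the pipeline can do under its own model
assumptions, not performance on arbitrary clinical data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_formats import AnnotationSet, SignalRecord
from .sequential_analysis import CycleWindowSpec, TemplateBasis

__all__ = [
    "WaveParams", "MATERNAL_WAVES", "FETAL_WAVES", "SynthConfig",
    "GroundTruth", "gaussian_beat", "synth_source", "generate_record",
    "noise_rms_for_snr",
]

# (amplitude, center offset from R in s, Gaussian width in s)
WaveParams = dict[str, tuple[float, float, float]]

MATERNAL_WAVES: WaveParams = {
    "P": (0.15, -0.16, 0.022),
    "Q": (-0.12, -0.025, 0.010),
    "R": (1.00, 0.0, 0.012),
    "S": (-0.20, 0.025, 0.010),
    "T": (0.30, 0.22, 0.055),
}

# narrower waves and shorter intervals for the fetal heart
FETAL_WAVES: WaveParams = {
    "P": (0.12, -0.10, 0.014),
    "Q": (-0.10, -0.016, 0.006),
    "R": (1.00, 0.0, 0.008),
    "S": (-0.18, 0.016, 0.006),
    "T": (0.25, 0.13, 0.035),
}


@dataclass(frozen=True)
class SynthConfig:
    """Generator settings; defaults are the package's study conditions.

    80 bpm maternal / 140 bpm fetal mean rates, 3% / 5% RR jitter,
    fetal-to-maternal R amplitude ratio 0.3, per-cycle section scalings
    uniform in [0.8, 1.2], and 20 dB SNR white noise on top of 0.25 Hz
    baseline wander and 50 Hz mains.
    """

    duration_s: float = 120.0
    fs: float = 500.0
    n_channels: int = 4
    maternal_bpm: float = 80.0
    maternal_rr_jitter: float = 0.03
    fetal_bpm: float = 140.0
    fetal_rr_jitter: float = 0.05
    fetal_amplitude_ratio: float = 0.3
    cycle_scaling_range: tuple[float, float] = (0.8, 1.2)
    noise_rms: float | None = None
    snr_db: float | None = 20.0
    baseline_amp: float = 0.15
    baseline_freq_hz: float = 0.25
    mains_freq_hz: float = 50.0
    mains_amp: float = 0.05
    mixing: np.ndarray | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fs <= 0 or self.duration_s <= 0:
            raise ValueError("fs and duration must be positive")
        if self.maternal_bpm <= 0 or self.fetal_bpm <= 0:
            raise ValueError("heart rates must be positive")
        if not 0.0 <= self.fetal_amplitude_ratio <= 1.0:
            raise ValueError("fetal amplitude ratio must lie in [0, 1]")
        lo, hi = self.cycle_scaling_range
        if not lo <= 1.0 <= hi:
            raise ValueError("cycle scaling range must contain 1")
        if self.n_channels < 1:
            raise ValueError("need at least 1 channel")
        if self.mixing is not None:
            mix = np.asarray(self.mixing, dtype=float)
            if mix.shape != (self.n_channels, 2):
                raise ValueError("mixing must have shape (n_channels, 2)")
            if np.any(np.all(mix == 0.0, axis=1)):
                raise ValueError("mixing has an all-zero channel row")
            object.__setattr__(self, "mixing", mix)


@dataclass(frozen=True)
class GroundTruth:
    """Everything the generator knows about the record it produced."""

    maternal_r: AnnotationSet
    fetal_r: AnnotationSet
    true_scalings: np.ndarray           # (n_maternal_beats, 3): P, QRS, T
    clean_sources: SignalRecord         # channels: (mECG, fECG), unmixed
    maternal_basis: TemplateBasis       # unscaled prototype sections


# default mixing weights: maternal dominates every electrode, the fetal
# contribution varies with (simulated) electrode placement
_DEF_MATERNAL_W = np.array([1.00, 0.85, 1.10, 0.75])
_DEF_FETAL_W = np.array([0.60, 1.00, 0.80, 0.50])


def _default_mixing(n_channels: int) -> np.ndarray:
    reps = int(np.ceil(n_channels / 4))
    mat = np.tile(_DEF_MATERNAL_W, reps)[:n_channels]
    fet = np.tile(_DEF_FETAL_W, reps)[:n_channels]
    return np.column_stack([mat, fet])


def gaussian_beat(fs: float, wave_params: WaveParams,
                  pre_s: float = 0.25, post_s: float = 0.45) -> np.ndarray:
    """Evaluate a sum-of-Gaussians beat on [−pre_s, post_s) around the R-peak."""
    n_pre = int(round(pre_s * fs))
    n_post = int(round(post_s * fs))
    t = (np.arange(-n_pre, n_post)) / fs
    beat = np.zeros_like(t)
    for amp, center, width in wave_params.values():
        if width <= 0:
            raise ValueError("wave widths must be positive")
        beat += amp * np.exp(-0.5 * ((t - center) / width) ** 2)
    return beat


def _beat_times(rate_bpm: float, jitter: float, duration_s: float,
                rng: np.random.Generator) -> np.ndarray:
    """R-peak times at jittered RR intervals (multiplicative Gaussian, ±3σ)."""
    mean_rr = 60.0 / rate_bpm
    times = []
    t = mean_rr  # first beat one mean interval in, so its window fits
    while t < duration_s:
        times.append(t)
        z = float(rng.standard_normal())
        factor = 1.0 + jitter * float(np.clip(z, -3.0, 3.0))
        t += mean_rr * factor
    if len(times) < 2:
        raise ValueError("rate and duration imply fewer than 2 beats")
    return np.asarray(times)


def synth_source(rate_bpm: float, jitter: float, *, fs: float, duration_s: float,
                 wave_params: WaveParams, pre_s: float, post_s: float,
                 amplitude: float = 1.0,
                 scaling_range: tuple[float, float] | None = None,
                 section_spec: CycleWindowSpec | None = None,
                 label: str = "maternal_ref",
                 rng: np.random.Generator) -> tuple[
                     SignalRecord, AnnotationSet, np.ndarray]:
    """Build one cardiac source: beats at jittered RR, per-cycle scaled sections.

    When ``scaling_range`` is given (with a ``section_spec`` describing
    the P/QRS/T split of the beat window), each beat's three sections
    are multiplied by an independently drawn triple; otherwise all
    triples are 1.  Returns (signal, true R-peaks, drawn scalings).
    """
    n = int(round(duration_s * fs))
    times = _beat_times(rate_bpm, jitter, duration_s, rng)
    r_indices = np.round(times * fs).astype(np.int64)
    r_indices = r_indices[r_indices < n]
    prototype = amplitude * gaussian_beat(fs, wave_params, pre_s, post_s)
    n_pre = int(round(pre_s * fs))

    if scaling_range is not None:
        if section_spec is None:
            raise ValueError("section scaling needs a CycleWindowSpec")
        n_p, n_qrs, n_t = section_spec.section_samples(fs)
        if n_p + n_qrs + n_t != prototype.size:
            raise ValueError("beat window does not match the section spec")
        lo, hi = scaling_range
        scalings = rng.uniform(lo, hi, size=(r_indices.size, 3))
    else:
        scalings = np.ones((r_indices.size, 3))
        n_p = n_qrs = n_t = 0

    signal = np.zeros(n)
    for k, r in enumerate(r_indices):
        beat = prototype.copy()
        if scaling_range is not None:
            beat[:n_p] *= scalings[k, 0]
            beat[n_p:n_p + n_qrs] *= scalings[k, 1]
            beat[n_p + n_qrs:] *= scalings[k, 2]
        start = int(r) - n_pre
        lo_i, hi_i = max(start, 0), min(start + beat.size, n)
        signal[lo_i:hi_i] += beat[lo_i - start:hi_i - start]
    record = SignalRecord(signal[np.newaxis, :], fs, (label.split("_")[0],))
    return record, AnnotationSet(r_indices, fs, label), scalings


def noise_rms_for_snr(clean_channels: np.ndarray, snr_db: float) -> float:
    """White-noise RMS giving ``snr_db`` against the clean channels' RMS."""
    signal_rms = float(np.sqrt(np.mean(clean_channels ** 2)))
    return signal_rms * 10.0 ** (-snr_db / 20.0)


def generate_record(cfg: SynthConfig = SynthConfig()) -> tuple[
        SignalRecord, GroundTruth]:
    """Generate a multichannel abdominal record and its ground truth."""
    root = np.random.SeedSequence(cfg.seed)
    rng_m, rng_f, rng_noise, rng_phase = (
        np.random.default_rng(s) for s in root.spawn(4)
    )
    spec = CycleWindowSpec()
    pre_m = spec.p_dur_s + spec.qrs_half_s     # 0.25 s
    post_m = spec.qrs_half_s + spec.t_dur_s    # 0.45 s

    mecg, maternal_r, scalings = synth_source(
        cfg.maternal_bpm, cfg.maternal_rr_jitter,
        fs=cfg.fs, duration_s=cfg.duration_s,
        wave_params=MATERNAL_WAVES, pre_s=pre_m, post_s=post_m,
        scaling_range=cfg.cycle_scaling_range, section_spec=spec,
        label="maternal_ref", rng=rng_m,
    )
    fecg, fetal_r, _ = synth_source(
        cfg.fetal_bpm, cfg.fetal_rr_jitter,
        fs=cfg.fs, duration_s=cfg.duration_s,
        wave_params=FETAL_WAVES, pre_s=0.15, post_s=0.25,
        amplitude=cfg.fetal_amplitude_ratio,
        label="fetal_ref", rng=rng_f,
    )

    mixing = cfg.mixing if cfg.mixing is not None else _default_mixing(cfg.n_channels)
    sources = np.vstack([mecg.samples[0], fecg.samples[0]])
    clean = mixing @ sources

    n = clean.shape[1]
    t = np.arange(n) / cfg.fs
    channels = clean.copy()
    for ch in range(cfg.n_channels):
        phase_b = rng_phase.uniform(0, 2 * np.pi)
        phase_m = rng_phase.uniform(0, 2 * np.pi)
        channels[ch] += cfg.baseline_amp * np.sin(
            2 * np.pi * cfg.baseline_freq_hz * t + phase_b
        )
        channels[ch] += cfg.mains_amp * np.sin(
            2 * np.pi * cfg.mains_freq_hz * t + phase_m
        )
    if cfg.snr_db is not None:
        noise_rms = noise_rms_for_snr(clean, cfg.snr_db)
    else:
        noise_rms = cfg.noise_rms or 0.0
    if noise_rms > 0:
        channels += noise_rms * rng_noise.standard_normal(channels.shape)

    record = SignalRecord(
        channels, cfg.fs,
        tuple(f"abd{i + 1}" for i in range(cfg.n_channels)),
        record_id="synthetic",
    )
    proto = gaussian_beat(cfg.fs, MATERNAL_WAVES, pre_m, post_m)
    n_p, n_qrs, n_t = spec.section_samples(cfg.fs)
    basis = TemplateBasis(
        mu_p=proto[:n_p], mu_qrs=proto[n_p:n_p + n_qrs], mu_t=proto[n_p + n_qrs:]
    )
    truth = GroundTruth(
        maternal_r=maternal_r,
        fetal_r=fetal_r,
        true_scalings=scalings,
        clean_sources=SignalRecord(sources, cfg.fs, ("mecg", "fecg"), "sources"),
        maternal_basis=basis,
    )
    return record, truth
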