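"""Evaluation protocols: detection statistics, fHR features, quality indices.

Three complementary views of extraction quality:

1. **R-peak detection accuracy.**  Detected fetal R-peaks are matched
   one-to-one to reference annotations within ±50 ms; from the TP/FP/FN
   counts ACC = TP/(TP+FP+FN), SE = TP/(TP+FN), PPV = TP/(TP+FP) (all
   ×100) and F1 = 2·SE·PPV/(SE+PPV).
2. **Clinically important features.**  The beat-to-beat fHR trace
   (60/RR, smoothed with a 30-beat centered moving average), the NICHD
   baseline rate (mean over up to 10 min, iteratively excluding 1-min
   segments deviating > 25 bpm) and the variability (median over 1-min
   windows of the peak-to-trough amplitude of the detrended trace).
3. **Signal quality indices.**  kSQI (sample kurtosis, Pearson
   convention — Gaussian = 3, values above 5 indicate a clean
   spike-dominated ECG) and sSQI (sample skewness), both population
   estimators.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .io_formats import AnnotationSet, SignalRecord

__all__ = [
    "DetectionStats", "FHRTrace", "ClinicalFeatures", "SQIReport",
    "RecordReport", "match_peaks", "compute_metrics", "fhr_trace",
    "baseline_rate", "variability", "ksqi", "ssqi", "evaluate_record",
    "plot_fhr_comparison",
]

MATCH_TOLERANCE_S = 0.05
SMOOTHING_WINDOW_BEATS = 30
BASELINE_EXCLUSION_BPM = 25.0


@dataclass(frozen=True)
class DetectionStats:
    """TP/FP/FN counts with the four derived percentages."""

    tp: int
    fp: int
    fn: int
    acc: float
    se: float
    ppv: float
    f1: float

    def rounded(self, ndigits: int = 2) -> "DetectionStats":
        """Display rounding (internally everything stays unrounded)."""
        rr = lambda v: float("nan") if math.isnan(v) else round(v, ndigits)
        return DetectionStats(self.tp, self.fp, self.fn, rr(self.acc),
                              rr(self.se), rr(self.ppv), rr(self.f1))


@dataclass(frozen=True)
class FHRTrace:
    """Beat-to-beat heart-rate series with its smoothed counterpart."""

    beat_times: np.ndarray   # time of the closing beat of each interval (s)
    bpm_raw: np.ndarray
    bpm_smooth: np.ndarray

    @property
    def duration_s(self) -> float:
        return float(self.beat_times[-1] - self.beat_times[0]) \
            if self.beat_times.size > 1 else 0.0


@dataclass(frozen=True)
class ClinicalFeatures:
    baseline_bpm: float
    variability_bpm: float


@dataclass(frozen=True)
class SQIReport:
    ksqi: float
    ssqi: float


@dataclass(frozen=True)
class RecordReport:
    """Bundle of all three evaluation protocols for one record."""

    stats: DetectionStats
    clinical_detected: ClinicalFeatures | None
    clinical_reference: ClinicalFeatures | None
    sqi: SQIReport
    trace_detected: FHRTrace | None
    trace_reference: FHRTrace | None

    def summary_frame(self) -> pd.DataFrame:
        """Comparison table of the headline numbers."""
        rows = {
            "TP": self.stats.tp, "FP": self.stats.fp, "FN": self.stats.fn,
            "ACC (%)": self.stats.acc, "SE (%)": self.stats.se,
            "PPV (%)": self.stats.ppv, "F1 (%)": self.stats.f1,
            "kSQI": self.sqi.ksqi, "sSQI": self.sqi.ssqi,
        }
        if self.clinical_detected is not None:
            rows["baseline est. (bpm)"] = self.clinical_detected.baseline_bpm
            rows["variability est. (bpm)"] = self.clinical_detected.variability_bpm
        if self.clinical_reference is not None:
            rows["baseline ref. (bpm)"] = self.clinical_reference.baseline_bpm
            rows["variability ref. (bpm)"] = self.clinical_reference.variability_bpm
        return pd.DataFrame({"value": rows})


def match_peaks(detected: AnnotationSet, reference: AnnotationSet,
                tol_s: float = MATCH_TOLERANCE_S) -> tuple[int, int, int]:
    """One-to-one greedy matching within ±``tol_s``; returns (tp, fp, fn).

    References are swept in order; each pairs with the nearest unmatched
    detection within tolerance (ties to the earlier detection).
    Unpaired detections are FP, unpaired references FN.
    """
    if detected.fs != reference.fs:
        raise ValueError(
            f"fs mismatch: detected {detected.fs} vs reference {reference.fs}"
        )
    tol = tol_s * reference.fs
    det = detected.indices
    used = np.zeros(det.size, dtype=bool)
    tp = 0
    for r in reference.indices:
        best_j = -1
        best_dist = tol + 1.0
        for j in range(det.size):
            if used[j]:
                continue
            dist = abs(float(det[j]) - float(r))
            if dist <= tol and dist < best_dist:  # strict: ties keep earlier j
                best_dist = dist
                best_j = j
        if best_j >= 0:
            used[best_j] = True
            tp += 1
    fp = int(det.size - tp)
    fn = int(reference.indices.size - tp)
    return tp, fp, fn


def compute_metrics(tp: int, fp: int, fn: int) -> DetectionStats:
    """ACC, SE, PPV and F1 (percentages) from the matching counts."""
    if min(tp, fp, fn) < 0:
        raise ValueError("counts must be non-negative")
    if tp + fp + fn == 0:
        raise ValueError("all counts are zero; nothing was detected or expected")
    if tp + fn == 0:
        raise ValueError("no reference peaks (TP+FN = 0); SE undefined")
    if tp + fp == 0:
        raise ValueError("no detections (TP+FP = 0); PPV undefined")
    acc = 100.0 * tp / (tp + fp + fn)
    se = 100.0 * tp / (tp + fn)
    ppv = 100.0 * tp / (tp + fp)
    f1 = 2.0 * se * ppv / (se + ppv) if (se + ppv) > 0 else 0.0
    return DetectionStats(int(tp), int(fp), int(fn), acc, se, ppv, f1)


def fhr_trace(r_peaks: AnnotationSet) -> FHRTrace:
    """Beat-to-beat heart rate 60·fs/ΔR with a 30-beat centered moving average.

    The smoothing window shrinks symmetrically at the edges so the
    smoothed series has the same length as the raw one.
    """
    if len(r_peaks) < 2:
        raise ValueError("need at least 2 peaks for an RR interval")
    idx = r_peaks.indices.astype(float)
    rr_samples = np.diff(idx)
    bpm_raw = 60.0 * r_peaks.fs / rr_samples
    smooth = (
        pd.Series(bpm_raw)
        .rolling(SMOOTHING_WINDOW_BEATS, center=True, min_periods=1)
        .mean()
        .to_numpy()
    )
    return FHRTrace(beat_times=idx[1:] / r_peaks.fs, bpm_raw=bpm_raw,
                    bpm_smooth=smooth)


def _minute_segments(trace: FHRTrace, limit_s: float) -> list[np.ndarray]:
    """Indices of the smoothed series grouped into 1-min bins up to limit_s."""
    t = trace.beat_times - trace.beat_times[0]
    segments = []
    for k in range(int(np.ceil(limit_s / 60.0))):
        mask = (t >= 60.0 * k) & (t < 60.0 * (k + 1)) & (t < limit_s)
        if mask.any():
            segments.append(np.flatnonzero(mask))
    return segments


def baseline_rate(trace: FHRTrace, round_to_5: bool = False) -> float:
    """NICHD-style baseline heart rate over at most the first 10 minutes.

    The mean of the smoothed trace is refined by repeatedly excluding
    1-min segments whose segment mean deviates more than 25 bpm from the
    current estimate (up to 10 passes).  ``round_to_5`` snaps the result
    to the nearest multiple of 5 bpm.
    """
    if trace.duration_s < 60.0:
        raise ValueError("trace shorter than 1 minute")
    limit = min(600.0, trace.duration_s)
    segments = _minute_segments(trace, limit)
    seg_means = np.array([trace.bpm_smooth[s].mean() for s in segments])
    seg_sizes = np.array([s.size for s in segments], dtype=float)
    included = np.ones(len(segments), dtype=bool)
    estimate = float(np.average(seg_means, weights=seg_sizes))
    for _ in range(10):
        keep = np.abs(seg_means - estimate) <= BASELINE_EXCLUSION_BPM
        if not keep.any():
            raise ValueError("all 1-min segments excluded; no stable baseline")
        if np.array_equal(keep, included):
            break
        included = keep
        estimate = float(np.average(seg_means[keep], weights=seg_sizes[keep]))
    if round_to_5:
        return 5.0 * round(estimate / 5.0)
    return estimate


def variability(trace: FHRTrace) -> float:
    """Median over 1-min windows of the peak-to-trough trace amplitude."""
    if trace.duration_s < 120.0:
        raise ValueError("trace shorter than 2 minutes")
    base = baseline_rate(trace)
    detrended = trace.bpm_smooth - base
    segments = _minute_segments(trace, trace.duration_s)
    amplitudes = [
        float(detrended[s].max() - detrended[s].min())
        for s in segments if s.size >= 2
    ]
    return float(np.median(amplitudes))


def _check_sqi_input(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float).ravel()
    if x.size < 4:
        raise ValueError("need at least 4 samples")
    if np.ptp(x) == 0:
        raise ValueError("constant signal; standardized moments undefined")
    return x


def ksqi(signal: SignalRecord | np.ndarray) -> float:
    """Kurtosis quality index (Pearson convention: Gaussian → 3)."""
    x = signal.samples[0] if isinstance(signal, SignalRecord) else signal
    x = _check_sqi_input(x)
    return float(sstats.kurtosis(x, fisher=False, bias=True))


def ssqi(signal: SignalRecord | np.ndarray) -> float:
    """Skewness quality index (third standardized moment)."""
    x = signal.samples[0] if isinstance(signal, SignalRecord) else signal
    x = _check_sqi_input(x)
    return float(sstats.skew(x, bias=True))


def evaluate_record(detected: AnnotationSet, reference: AnnotationSet,
                    extracted: SignalRecord) -> RecordReport:
    """Run all three protocols; undefined ratios are reported as NaN."""
    tp, fp, fn = match_peaks(detected, reference)
    acc = 100.0 * tp / (tp + fp + fn) if (tp + fp + fn) else float("nan")
    se = 100.0 * tp / (tp + fn) if (tp + fn) else float("nan")
    ppv = 100.0 * tp / (tp + fp) if (tp + fp) else float("nan")
    f1 = (2.0 * se * ppv / (se + ppv)
          if np.isfinite(se) and np.isfinite(ppv) and (se + ppv) > 0
          else float("nan"))
    stats = DetectionStats(tp, fp, fn, acc, se, ppv, f1)

    def _clinical(ann: AnnotationSet) -> tuple[FHRTrace | None,
                                               ClinicalFeatures | None]:
        try:
            trace = fhr_trace(ann)
        except ValueError:
            return None, None
        try:
            features = ClinicalFeatures(baseline_rate(trace), variability(trace))
        except ValueError:
            features = None
        return trace, features

    trace_det, clin_det = _clinical(detected)
    trace_ref, clin_ref = _clinical(reference)
    sqi = SQIReport(ksqi(extracted), ssqi(extracted))
    return RecordReport(stats, clin_det, clin_ref, sqi, trace_det, trace_ref)


def plot_fhr_comparison(report: RecordReport, path: str) -> str:
    """Plot estimated vs. reference fHR traces to an image file."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(9, 3.2))
    if report.trace_reference is not None:
        ax.plot(report.trace_reference.beat_times,
                report.trace_reference.bpm_smooth, "r-", label="reference")
    if report.trace_detected is not None:
        ax.plot(report.trace_detected.beat_times,
                report.trace_detected.bpm_smooth, "k-", label="estimated")
    ax.set_xlabel("time (s)")
    ax.set_ylabel("fHR (bpm)")
    ax.legend(loc="best")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
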