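import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import maximum_bipartite_matching

from fecg_sagwo.evaluation import (DetectionStats, FHRTrace, baseline_rate,
                                   compute_metrics, evaluate_record,
                                   fhr_trace, ksqi, match_peaks, ssqi,
                                   variability)
from fecg_sagwo.io_formats import AnnotationSet, SignalRecord
from fecg_sagwo.reference_data import (LABOUR_COUNTS, PREGNANCY_COUNTS,
                                       dataset_mean_metrics)

FS = 500.0


def ann(indices, label="fetal_det"):
    return AnnotationSet(np.array(indices, dtype=np.int64), FS, label)


def optimal_match_count(det, ref, tol):
    """Oracle: maximum one-to-one matching cardinality (bipartite)."""
    if len(det) == 0 or len(ref) == 0:
        return 0
    adj = np.abs(np.subtract.outer(list(ref), list(det))) <= tol
    match = maximum_bipartite_matching(csr_matrix(adj.astype(int)),
                                       perm_type="column")
    return int(np.sum(match >= 0))


class TestMatchPeaks:
    @pytest.mark.parametrize("det,ref,expected", [
        ([110], [100], (1, 0, 0)),      # 20 ms apart: inside +-50 ms
        ([130], [100], (0, 1, 1)),      # 60 ms apart: outside
        ([100, 101, 200], [100, 200], (2, 1, 0)),
    ])
    def test_reference_cases(self, det, ref, expected):
        assert match_peaks(ann(det), ann(ref, "fetal_ref")) == expected

    def test_count_bookkeeping_on_random_instances(self):
        rng = np.random.default_rng(0)
        for _ in range(1000):
            ref = np.unique(rng.integers(0, 5000, size=rng.integers(0, 12)))
            det = np.unique(rng.integers(0, 5000, size=rng.integers(0, 12)))
            tp, fp, fn = match_peaks(ann(det), ann(ref, "fetal_ref"))
            assert tp + fn == len(ref)
            assert tp + fp == len(det)

    def test_greedy_agrees_with_optimal_on_spaced_instances(self):
        # realistic instances: references spaced beyond twice the tolerance
        rng = np.random.default_rng(1)
        tol = int(0.05 * FS)
        for _ in range(300):
            n_ref = rng.integers(1, 9)
            ref = np.cumsum(rng.integers(3 * tol, 12 * tol, size=n_ref))
            jitter = rng.integers(-2 * tol, 2 * tol, size=n_ref)
            keep = rng.random(n_ref) > 0.2
            det = np.unique(np.concatenate([
                (ref + jitter)[keep],
                rng.integers(0, int(ref[-1]) + tol, size=rng.integers(0, 3)),
            ]))
            det = det[det >= 0]
            tp, fp, fn = match_peaks(ann(det), ann(ref, "fetal_ref"))
            assert tp == optimal_match_count(det, ref, tol)

    def test_swap_symmetry(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            a = np.unique(rng.integers(0, 3000, size=8))
            b = np.unique(rng.integers(0, 3000, size=8))
            tp1, fp1, fn1 = match_peaks(ann(a), ann(b, "fetal_ref"))
            tp2, fp2, fn2 = match_peaks(ann(b), ann(a, "fetal_ref"))
            assert (tp1, fp1, fn1) == (tp2, fn2, fp2)

    def test_fs_mismatch_rejected(self):
        other = AnnotationSet(np.array([1]), 250.0, "fetal_ref")
        with pytest.raises(ValueError, match="fs"):
            match_peaks(ann([1]), other)


# printed benchmark rows: record -> (ACC, SE, PPV, F1) at 2 decimals
LABOUR_METRICS = {
    "r01": (98.61, 99.38, 99.22, 99.30), "r02": (95.33, 96.08, 99.19, 97.61),
    "r03": (58.13, 76.40, 70.85, 73.52), "r04": (96.69, 98.53, 98.10, 98.32),
    "r05": (97.90, 98.94, 98.94, 98.94), "r06": (97.97, 98.83, 99.12, 98.98),
    "r07": (96.42, 97.94, 98.41, 98.18), "r08": (99.84, 99.84, 100.00, 99.92),
    "r09": (97.51, 98.81, 98.67, 98.74), "r10": (100.00, 100.00, 100.00, 100.00),
    "r11": (97.56, 99.07, 98.46, 98.77), "r12": (99.24, 99.70, 99.54, 99.62),
}
PREGNANCY_METRICS = {
    "r01": (98.85, 99.45, 99.39, 99.42), "r02": (94.44, 96.17, 98.14, 97.14),
    "r03": (95.46, 96.25, 99.15, 97.68), "r04": (99.28, 99.50, 99.78, 99.64),
    "r05": (99.68, 99.93, 99.75, 99.84), "r06": (94.40, 97.74, 96.50, 97.12),
    "r07": (92.19, 95.67, 96.20, 95.94), "r08": (96.72, 98.86, 97.81, 98.33),
    "r09": (97.62, 98.97, 98.62, 98.79), "r10": (88.00, 93.96, 93.27, 93.62),
}


class TestComputeMetrics:
    @pytest.mark.parametrize("counts,expected", [
        *[(LABOUR_COUNTS[r], LABOUR_METRICS[r]) for r in LABOUR_COUNTS],
        *[(PREGNANCY_COUNTS[r], PREGNANCY_METRICS[r]) for r in PREGNANCY_COUNTS],
    ])
    def test_benchmark_rows_reproduce(self, counts, expected):
        s = compute_metrics(*counts).rounded()
        assert (s.acc, s.se, s.ppv, s.f1) == expected

    def test_dataset_means_match_published_averages(self):
        labour = dataset_mean_metrics(LABOUR_COUNTS)
        assert round(labour["acc"], 2) == 94.60
        assert round(labour["f1"], 2) == 96.82
        assert round(dataset_mean_metrics(PREGNANCY_COUNTS)["acc"], 2) == 95.66

    def test_f1_algebraic_identity(self):
        rng = np.random.default_rng(3)
        for _ in range(200):
            tp = int(rng.integers(1, 1000))
            fp = int(rng.integers(0, 300))
            fn = int(rng.integers(0, 300))
            s = compute_metrics(tp, fp, fn)
            alt = 100.0 * 2 * tp / (2 * tp + fp + fn)
            assert s.f1 == pytest.approx(alt, abs=1e-9)

    @pytest.mark.parametrize("counts", [(0, 0, 0), (0, 5, 0), (0, 0, 5)])
    def test_degenerate_counts_rejected(self, counts):
        with pytest.raises(ValueError):
            compute_metrics(*counts)

    @settings(max_examples=200, derandomize=True)
    @given(tp=st.integers(1, 10_000), fp=st.integers(0, 10_000),
           fn=st.integers(0, 10_000))
    def test_metric_invariants_hold_for_any_counts(self, tp, fp, fn):
        """All four percentages lie in [0, 100], ACC never exceeds SE or
        PPV, and F1 sits between min and max of SE and PPV."""
        s = compute_metrics(tp, fp, fn)
        for v in (s.acc, s.se, s.ppv, s.f1):
            assert 0.0 <= v <= 100.0
        assert s.acc <= s.se + 1e-9 and s.acc <= s.ppv + 1e-9
        assert min(s.se, s.ppv) - 1e-9 <= s.f1 <= max(s.se, s.ppv) + 1e-9


class TestFhrTrace:
    def test_constant_rr(self):
        peaks = ann(np.arange(0, 50) * int(0.5 * FS))
        trace = fhr_trace(peaks)
        np.testing.assert_allclose(trace.bpm_raw, 120.0)
        np.testing.assert_allclose(trace.bpm_smooth, 120.0)

    def test_alternating_rr(self):
        rr = np.tile([int(0.4 * FS), int(0.6 * FS)], 40)
        peaks = ann(np.concatenate([[0], np.cumsum(rr)]))
        trace = fhr_trace(peaks)
        np.testing.assert_allclose(trace.bpm_raw[::2], 150.0)
        np.testing.assert_allclose(trace.bpm_raw[1::2], 100.0)
        assert np.all(np.abs(trace.bpm_smooth[30:-30] - 125.0) <= 1.0)

    def test_too_few_peaks_rejected(self):
        with pytest.raises(ValueError):
            fhr_trace(ann([100]))


def synthetic_trace(bpm_series, fs=4.0):
    """Build an FHRTrace directly from a smoothed bpm series (fs in beats/s)."""
    t = np.arange(len(bpm_series)) / fs
    series = np.asarray(bpm_series, dtype=float)
    return FHRTrace(beat_times=t, bpm_raw=series, bpm_smooth=series)


class TestBaselineRate:
    def test_constant_trace(self):
        trace = synthetic_trace(np.full(2400, 140.0))  # 10 min at 4 beats/s
        assert baseline_rate(trace) == pytest.approx(140.0)
        assert baseline_rate(trace, round_to_5=True) == 140.0

    def test_rounding_to_nearest_five(self):
        trace = synthetic_trace(np.full(1200, 142.0))
        assert baseline_rate(trace, round_to_5=True) == 140.0

    def test_excursion_minute_excluded(self):
        series = np.full(2400, 140.0)
        series[240:480] += 30.0  # one 1-min segment at 170 bpm
        trace = synthetic_trace(series)
        assert baseline_rate(trace) == pytest.approx(140.0, abs=0.5)

    def test_short_trace_rejected(self):
        with pytest.raises(ValueError):
            baseline_rate(synthetic_trace(np.full(100, 140.0)))


class TestVariability:
    def test_constant_trace_zero(self):
        assert variability(synthetic_trace(np.full(2400, 140.0))) == 0.0

    def test_sinusoidal_fluctuation_amplitude(self):
        t = np.arange(2400) / 4.0
        series = 140.0 + 5.0 * np.sin(2 * np.pi * t / 30.0)
        assert variability(synthetic_trace(series)) == pytest.approx(10.0,
                                                                     rel=0.10)

    def test_median_robust_to_one_noisy_minute(self):
        rng = np.random.default_rng(0)
        series = np.full(2400, 140.0) + np.sin(np.arange(2400) / 20.0)
        series[480:720] += rng.normal(0, 15.0, 240)  # one wild minute
        v = variability(synthetic_trace(series))
        assert v < 5.0


class TestSqi:
    def test_gaussian_moments(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(10 ** 6)
        assert ksqi(x) == pytest.approx(3.0, abs=0.05)
        assert ssqi(x) == pytest.approx(0.0, abs=0.01)

    def test_laplace_kurtosis(self):
        rng = np.random.default_rng(1)
        x = rng.laplace(size=10 ** 6)
        assert ksqi(x) == pytest.approx(6.0, abs=0.2)

    def test_exponential_skewness(self):
        rng = np.random.default_rng(2)
        x = rng.exponential(size=10 ** 6)
        assert ssqi(x) == pytest.approx(2.0, abs=0.02)

    def test_constant_signal_rejected(self):
        with pytest.raises(ValueError):
            ksqi(np.ones(100))


class TestEvaluateRecord:
    def _signal(self):
        rng = np.random.default_rng(5)
        return SignalRecord(rng.standard_normal((1, 2000)), fs=FS)

    def test_perfect_detection(self):
        peaks = ann(np.arange(2, 200) * int(0.43 * FS), "fetal_det")
        ref = AnnotationSet(peaks.indices, FS, "fetal_ref")
        report = evaluate_record(peaks, ref, self._signal())
        s = report.stats
        assert (s.fp, s.fn) == (0, 0)
        assert s.acc == s.se == s.ppv == s.f1 == 100.0
        np.testing.assert_array_equal(report.trace_detected.bpm_smooth,
                                      report.trace_reference.bpm_smooth)

    def test_empty_detection_reports_nan_ppv(self):
        det = ann([], "fetal_det")
        ref = ann([100, 400, 800], "fetal_ref")
        report = evaluate_record(det, ref, self._signal())
        assert report.stats.se == 0.0
        assert np.isnan(report.stats.ppv) and np.isnan(report.stats.f1)

    def test_end_to_end_report_is_finite(self, default_record):
        record, truth = default_record
        report = evaluate_record(
            AnnotationSet(truth.fetal_r.indices, FS, "fetal_det"),
            truth.fetal_r, record.channel(0))
        assert np.isfinite(report.sqi.ksqi) and np.isfinite(report.sqi.ssqi)
        frame = report.summary_frame()
        assert np.isfinite(frame.loc["ACC (%)", "value"])
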