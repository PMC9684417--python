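"""Per-beat maternal template model: windowing, basis, scaling, subtraction.

Each maternal cardiac cycle is modelled as three independently scaled
sections around the detected R-peak:

* QRS — 0.05 s before to 0.05 s after the R-peak,
* P   — the 0.20 s ending where the QRS window begins,
* T   — the 0.40 s starting where the QRS window ends,

for a total window of 0.70 s.  The averaged section waveforms
``mu_P, mu_QRS, mu_T`` are stacked into the block matrix::

    M = [[mu_P, 0,      0   ],
         [0,    mu_QRS, 0   ],
         [0,    0,      mu_T]]          (window_samples x 3)

so that a cycle m is approximated by the template ``m_hat = M a`` with
the scaling triple ``a = (a_P, a_QRS, a_T)``.  Because the blocks are
disjoint, the least-squares solution ``a = (M'M)^{-1} M' m`` reduces to
per-section projections ``<mu_s, m_s> / ||mu_s||^2``, and the squared
residual ``e^2 = ||m - M a||^2`` is the quantity the optimizer in the
full pipeline minimises per beat (as a mean square).

Windows are half-open ``[start, end)`` in 0-based samples.  Beats whose
window runs past the record edges, or whose T section would overlap the
next beat's P window, are flagged *truncated*: they are still cancelled
with a row-truncated template but excluded from basis averaging.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_formats import AnnotationSet, SignalRecord

__all__ = [
    "CycleWindowSpec", "CycleSegments", "TemplateBasis", "ScalingVector",
    "TemplateFit", "segment_cycles", "average_cycles", "build_matrix",
    "ls_scaling", "fit_template", "subtract_templates",
]


class RankError(np.linalg.LinAlgError):
    """The block matrix has a zero-norm column; the scaling is undefined."""


@dataclass(frozen=True)
class CycleWindowSpec:
    """Section durations of the 0.70 s maternal cycle window (seconds)."""

    qrs_half_s: float = 0.05
    p_dur_s: float = 0.20
    t_dur_s: float = 0.40

    def __post_init__(self) -> None:
        if min(self.qrs_half_s, self.p_dur_s, self.t_dur_s) <= 0:
            raise ValueError("all window durations must be positive")

    @property
    def total_s(self) -> float:
        return self.p_dur_s + 2 * self.qrs_half_s + self.t_dur_s

    def section_samples(self, fs: float) -> tuple[int, int, int]:
        """(n_p, n_qrs, n_t) sample counts at rate ``fs``."""
        n_p = int(round(self.p_dur_s * fs))
        n_qrs = 2 * int(round(self.qrs_half_s * fs))
        n_t = int(round(self.t_dur_s * fs))
        if min(n_p, n_qrs, n_t) < 2:
            raise ValueError(
                f"sampling rate {fs} Hz gives a section of < 2 samples"
            )
        return n_p, n_qrs, n_t

    def window_samples(self, fs: float) -> int:
        return sum(self.section_samples(fs))


@dataclass(frozen=True)
class CycleSegments:
    """One beat's windowed sections.

    ``start``/``end`` are the actual (possibly truncated) absolute
    sample bounds; ``row_start``/``row_end`` locate those samples as
    rows of the nominal full window (and hence of the block matrix).
    """

    beat_index: int
    r_peak: int
    p: np.ndarray
    qrs: np.ndarray
    t: np.ndarray
    start: int
    end: int
    row_start: int
    row_end: int
    truncated: bool

    @property
    def cycle(self) -> np.ndarray:
        """The windowed samples m, sections concatenated."""
        return np.concatenate([self.p, self.qrs, self.t])


@dataclass(frozen=True)
class TemplateBasis:
    """Averaged section waveforms and the assembled block matrix."""

    mu_p: np.ndarray
    mu_qrs: np.ndarray
    mu_t: np.ndarray

    @property
    def matrix_m(self) -> np.ndarray:
        return build_matrix(self)


@dataclass(frozen=True)
class ScalingVector:
    """Dimensionless per-section multipliers (a_P, a_QRS, a_T)."""

    a_p: float
    a_qrs: float
    a_t: float

    def __post_init__(self) -> None:
        if not np.all(np.isfinite([self.a_p, self.a_qrs, self.a_t])):
            raise ValueError("scaling values must be finite")

    def as_array(self) -> np.ndarray:
        return np.array([self.a_p, self.a_qrs, self.a_t])

    @classmethod
    def from_array(cls, a: np.ndarray) -> "ScalingVector":
        a = np.asarray(a, dtype=float).ravel()
        return cls(float(a[0]), float(a[1]), float(a[2]))


@dataclass(frozen=True)
class TemplateFit:
    """A fitted template m_hat = M a and its squared residual e^2."""

    template: np.ndarray
    residual_sq: float


def segment_cycles(record: SignalRecord, r_peaks: AnnotationSet,
                   spec: CycleWindowSpec = CycleWindowSpec()) -> list[CycleSegments]:
    """Split a single-channel record into per-beat P/QRS/T sections.

    A beat is flagged truncated when its window runs past a record edge,
    when its T section is cut short by the next beat's P window, or when
    the previous beat's window overlaps its own (the overlapped samples
    carry the neighbour's tail and would bias the basis average).
    """
    if record.n_channels != 1:
        raise ValueError("segment_cycles expects a single-channel record")
    n_p, n_qrs, n_t = spec.section_samples(record.fs)
    half = n_qrs // 2
    x = record.samples[0]
    n = x.size
    peaks = r_peaks.indices
    segments: list[CycleSegments] = []
    for i, r in enumerate(peaks):
        r = int(r)
        nominal_start = r - half - n_p
        nominal_end = r + half + n_t
        start = max(nominal_start, 0)
        end = min(nominal_end, n)
        if i + 1 < peaks.size:
            next_p_start = int(peaks[i + 1]) - half - n_p
            end = min(end, max(next_p_start, start))
        truncated = (start != nominal_start) or (end != nominal_end)
        if i > 0 and int(peaks[i - 1]) + half + n_t > nominal_start:
            # previous beat's nominal window bleeds into this one
            truncated = True
        row_start = start - nominal_start
        row_end = end - nominal_start
        window = x[start:end]
        # section boundaries in full-window rows
        b1, b2 = n_p, n_p + n_qrs
        offs = np.arange(row_start, row_end)
        segments.append(CycleSegments(
            beat_index=i, r_peak=r,
            p=window[offs < b1].copy(),
            qrs=window[(offs >= b1) & (offs < b2)].copy(),
            t=window[offs >= b2].copy(),
            start=start, end=end,
            row_start=row_start, row_end=row_end,
            truncated=truncated,
        ))
    return segments


def average_cycles(segments: list[CycleSegments]) -> TemplateBasis:
    """Per-sample arithmetic mean of the non-truncated beats' sections."""
    usable = [s for s in segments if not s.truncated]
    if not usable:
        raise ValueError("no non-truncated beats to average")
    return TemplateBasis(
        mu_p=np.mean([s.p for s in usable], axis=0),
        mu_qrs=np.mean([s.qrs for s in usable], axis=0),
        mu_t=np.mean([s.t for s in usable], axis=0),
    )


def build_matrix(basis: TemplateBasis) -> np.ndarray:
    """Assemble the (window x 3) block matrix from the averaged sections."""
    n_p, n_qrs, n_t = basis.mu_p.size, basis.mu_qrs.size, basis.mu_t.size
    m = np.zeros((n_p + n_qrs + n_t, 3))
    m[:n_p, 0] = basis.mu_p
    m[n_p:n_p + n_qrs, 1] = basis.mu_qrs
    m[n_p + n_qrs:, 2] = basis.mu_t
    return m


def ls_scaling(matrix_m: np.ndarray, cycle_m: np.ndarray) -> ScalingVector:
    """Closed-form least-squares scaling a = (M'M)^{-1} M' m.

    Raises :class:`RankError` when any column has zero norm (the normal
    equations are then singular).
    """
    matrix_m = np.asarray(matrix_m, dtype=float)
    cycle_m = np.asarray(cycle_m, dtype=float).ravel()
    if cycle_m.size != matrix_m.shape[0]:
        raise ValueError(
            f"cycle of {cycle_m.size} samples vs matrix of "
            f"{matrix_m.shape[0]} rows"
        )
    gram = matrix_m.T @ matrix_m
    if np.any(np.diag(gram) <= 0.0):
        raise RankError("block matrix has a zero-norm column")
    return ScalingVector.from_array(np.linalg.solve(gram, matrix_m.T @ cycle_m))


def partial_ls_scaling(matrix_m: np.ndarray, cycle_m: np.ndarray) -> ScalingVector:
    """LS scaling tolerant of empty sections (row-truncated beats).

    Coefficients of zero-norm columns are set to 0; they multiply an
    all-zero column, so the fitted template is unaffected.
    """
    matrix_m = np.asarray(matrix_m, dtype=float)
    cycle_m = np.asarray(cycle_m, dtype=float).ravel()
    norms = np.einsum("ij,ij->j", matrix_m, matrix_m)
    live = norms > 0.0
    a = np.zeros(3)
    if live.any():
        sub = matrix_m[:, live]
        a[live] = np.linalg.solve(sub.T @ sub, sub.T @ cycle_m)
    return ScalingVector.from_array(a)


def fit_template(matrix_m: np.ndarray, a: ScalingVector,
                 cycle_m: np.ndarray) -> TemplateFit:
    """Template m_hat = M a and squared residual e^2 = ||m - M a||^2."""
    template = np.asarray(matrix_m, dtype=float) @ a.as_array()
    diff = np.asarray(cycle_m, dtype=float).ravel() - template
    return TemplateFit(template=template, residual_sq=float(diff @ diff))


def subtract_templates(record: SignalRecord, r_peaks: AnnotationSet,
                       fits: list[TemplateFit],
                       spec: CycleWindowSpec = CycleWindowSpec()) -> SignalRecord:
    """Subtract each beat's fitted template over its (truncated) window.

    ``fits`` must align one-to-one with :func:`segment_cycles` output for
    the same record, peaks and window spec; samples outside every beat
    window are untouched.
    """
    segments = segment_cycles(record, r_peaks, spec)
    if len(fits) != len(segments):
        raise ValueError(f"{len(fits)} fits for {len(segments)} beats")
    out = record.samples.copy()
    for seg, fit in zip(segments, fits):
        if fit.template.size != seg.end - seg.start:
            raise ValueError(
                f"beat {seg.beat_index}: template of {fit.template.size} "
                f"samples for a {seg.end - seg.start}-sample window"
            )
        out[0, seg.start:seg.end] -= fit.template
    return record.with_samples(out)
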