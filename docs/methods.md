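# Methods

## The extraction problem

Electrodes on a pregnant woman's abdomen record a mixture: a dominant
maternal ECG (mECG), a fetal ECG (fECG) an order of magnitude weaker,
baseline wander, mains interference and broadband noise, all
overlapping in time and frequency. Recovering the fetal R-peaks — and
from them the fetal heart rate (fHR) trace used clinically — requires
cancelling the maternal component without touching the fetal spikes
buried inside it.

## Sequential-analysis template model

Each maternal beat is modelled as three independently scaled sections
around the detected R-peak at sampling rate `fs`:

- QRS: `[R − 0.05 s, R + 0.05 s)`
- P:   the 0.20 s ending where the QRS window begins
- T:   the 0.40 s starting where the QRS window ends

for a 0.70 s total window (all windows half-open, 0-based samples).
The placement of P before and T after the QRS window is the only
reading of the section durations consistent with the 0.70 s total; the
durations are configurable (`CycleWindowSpec`).

The averaged section waveforms `mu_P, mu_QRS, mu_T` (arithmetic mean
over all non-truncated beats of the record — a single global basis,
refit per beat through scaling) are stacked into the block matrix

    M = [[mu_P, 0, 0], [0, mu_QRS, 0], [0, 0, mu_T]]   (window × 3)

so a cycle `m` is approximated by `m̂ = M a` with scaling triple
`a = (a_P, a_QRS, a_T)`. Because the blocks are disjoint, `MᵀM` is
diagonal and the least-squares solution `a = (MᵀM)⁻¹Mᵀm` reduces to
per-section projections; the squared residual `e² = ‖m − M a‖²` is the
quantity minimised per beat. The per-beat objective handed to the
optimizer is the mean squared error (the sum of squares divided by the
window length — same argmin, better-conditioned magnitudes).

**Overlapping beats.** When an RR interval is shorter than 0.70 s, the
leading beat's T window is truncated where the next beat's P window
begins, and *both* beats involved are flagged: the follower's window
contains the leader's tail, which would bias the basis average and
breaks exact per-beat modelling. Flagged beats are still cancelled
(with row-truncated templates) but excluded from basis averaging.

## Grey wolf optimizer

The per-beat scaling is found by a grey wolf optimizer (GWO): a
population of agents whose three best-ever solutions (alpha, beta,
delta) steer every move,

    A = 2·a·r1 − a,  C = 2·r2,  D_L = |C·L − X|,  X_L = L − A·D_L,
    X(t+1) = (X_α + X_β + X_δ)/3,

with `a` decaying linearly from 2 to 0 over the run and `r1, r2`
uniform on [0, 1], drawn fresh per dimension, per leader, per agent,
per iteration. Out-of-bounds positions are clipped to the search box;
leader updates scan agents in index order with strict improvement, so
ties break to the lower index and a fixed seed gives bit-identical
results. The best-ever alpha is retained even when the swarm moves
away, making the fitness history monotone non-increasing. Omega wolves
are not modelled as a separate class — all non-leader agents follow the
same update, which is all the update equations use.

Default budget: 10 agents × 10 iterations (the configuration at which
the method is reported to work well); the per-beat random streams are
derived deterministically from the pipeline seed and the (channel,
beat) pair, so only one seed governs a whole extraction.

**Search bounds.** The scaling box defaults to `[0.5, 1.5]³`. Two
reasons. Physiological: per-cycle morphology modulation stays well
within ±50 % of the averaged template (the synthetic generator draws
from [0.8, 1.2]), and sign flips are non-physical for template scaling.
Numerical: the GWO step in each coordinate is proportional to
`|C·leader − x|`, so if the leaders' value in a weakly-observed
coordinate (typically the low-amplitude P section) nears zero, the step
size in that coordinate collapses and the swarm freezes at the origin.
With a box centered on zero (e.g. [−2, 2]³) roughly one cold run in
ten ends far above the closed-form optimum with `a_P` stuck near 0;
with the origin excluded the search reaches the optimum essentially
always, even at the 10 × 10 budget. The bounds are configurable for
records where larger modulation is expected.

A `warm_start` flag places one initial agent at the neutral scaling
(1, 1, 1); it is off by default (agents start at random positions).

Since the objective is a convex quadratic, the closed-form LS scaling
is the global optimum; the pipeline computes it alongside every GWO
solution and asserts `gwo_mse ≥ ls_mse` on every beat. This dual route
is also the acceptance check: at 10 × 50 the GWO lands within 5 % of
the LS optimum on ≥ 90 % of noisy beats.

## Pipeline

1. **Preprocessing.** Per channel, zero-phase (forward-backward)
   order-4 Butterworth high-pass at 1.0 Hz (baseline wander; 1 Hz
   preserves P/T morphology) and a second-order IIR notch at 50 Hz,
   Q = 30 (configurable to 60 Hz). The source method names the
   artifacts removed but not the filters; these are standard ECG
   practice and the package's own choice.
2. **Maternal reference.** PCA over the channels (centered, not
   variance-scaled — channels share units and amplitude dominance is
   the signal); component 1 is the maternal reference, since the
   maternal component dominates abdominal mixtures.
3. **Maternal R-peaks** on the reference (detector below).
4. **Cancellation**, per abdominal channel independently at the common
   maternal R-peaks: segment, average basis, per-beat GWO scaling,
   subtract. (Whether cancellation runs per channel or on a single
   component is an open choice; per-channel matches a 4-electrode
   front-end feeding cancellation with PCA afterwards.)
5. **Fetal enhancement.** PCA over the residual channels; the component
   with the highest sample kurtosis — the most spike-like — is the
   enhanced fetal channel (kurtosis is also the kSQI quality index;
   ties break to the lower component index).
6. **Fetal R-peaks** on the enhanced component.

Single-channel records skip both PCA stages.

## QRS detector

A Pan–Tompkins-style energy detector: zero-phase band-pass →
derivative → square → moving-window integration → adaptive threshold
(`threshold_factor` × running median of the last 8 accepted peak
energies, seeded from the strongest candidate in the first 2 s) →
refractory enforcement → refinement of each detection to the local
absolute extremum of the band-passed signal within ±25 ms.

Presets:

| preset   | band (Hz) | refractory (s) | integration (ms) | threshold |
|----------|-----------|----------------|------------------|-----------|
| maternal | 5–15      | 0.35           | 150              | 0.40      |
| fetal    | 10–30     | 0.25           | 100              | 0.15      |

The fetal preset deviates from adult conventions deliberately. The
integration window is 100 ms because at 140+ bpm a 150 ms window spans
a third of the RR interval and smears neighbouring maternal residue
into the fetal peak. The threshold factor is 0.15 because a fetal beat
that coincides with a maternal QRS loses part of its energy to the
template's QRS scaling (the scaled template partially absorbs the
overlapping spike) and an adult-calibrated threshold then rejects the
surviving, attenuated peak. Fetal beats landing within a few samples
of a maternal R-peak remain the dominant residual error mode — they are
absorbed almost entirely and no threshold recovers them.

## Evaluation protocols

1. **Detection accuracy.** Greedy one-to-one matching within ±50 ms
   (references swept in order, each paired with the nearest unmatched
   detection; ties to the earlier detection). This guarantees
   `TP + FN = |reference|` and `TP + FP = |detected|`; for realistic
   peak trains (references spaced beyond twice the tolerance) it equals
   optimal bipartite matching, which the tests verify by brute force.
   Metrics: ACC = TP/(TP+FP+FN), SE = TP/(TP+FN), PPV = TP/(TP+FP)
   (×100), F1 = 2·SE·PPV/(SE+PPV). Computed unrounded, displayed at
   2 decimals.
2. **Clinical features.** Beat-to-beat fHR = 60·fs/ΔR, smoothed with a
   30-beat centered moving average (shrinking symmetrically at the
   edges); the "30 samples" of the smoothing window are beat-to-beat
   values, since the trace is indexed by beats. Baseline rate: mean of
   the smoothed trace over at most the first 10 min, iteratively
   excluding 1-min segments deviating > 25 bpm from the running
   estimate (the only quantitative criterion in the NICHD definition),
   up to 10 passes; rounding to the nearest 5 bpm is an optional flag,
   off by default. Variability: median over non-overlapping 1-min
   windows of the peak-to-trough amplitude of the baseline-detrended
   smoothed trace.
3. **Quality indices.** kSQI = fourth standardized moment in the
   Pearson convention (Gaussian → 3, so the kSQI > 5 high-quality rule
   is meaningful) and sSQI = third standardized moment, both biased
   (population) estimators.

## Synthetic data generator

Each cardiac source is a train of sum-of-Gaussians beats (P, Q, R, S, T
waves). The maternal beat occupies exactly the 0.70 s analysis window,
and each cycle's P/QRS/T sections are multiplied by factors drawn
uniformly from [0.8, 1.2] — so a generated cycle is *exactly* a
block-scaled copy of the prototype sections and the closed-form scaling
recovers the drawn triples to machine precision on the clean source
(the loop-closing oracle for the template model). A sum-of-Gaussians
model was chosen over a dynamical-system ECG model precisely because
its sections map exactly onto the analysis windows.

Study conditions (the defaults): 500 Hz, 4 channels, 120 s; maternal
80 bpm with 3 % multiplicative RR jitter (truncated ±3σ), fetal 140 bpm
with 5 % jitter; fetal/maternal R amplitude ratio 0.3; fixed channel
mixing (maternal weights 1.00/0.85/1.10/0.75, fetal
0.60/1.00/0.80/0.50); 0.25 Hz baseline wander of amplitude 0.15,
50 Hz mains of amplitude 0.05, and white noise at 20 dB SNR relative
to the clean mixed signal (`snr_db` and `noise_rms` are alternative
specifications).

What the generator does *not* emulate: electrode motion artifacts,
uterine EMG, fetal position changes, non-stationary mixing, and
morphological dispersion between the fetal body and the abdominal
surface. Passing results on synthetic records show the pipeline works
under its own model assumptions, not that it matches the published
real-data numbers; those require the clinical recordings themselves.

## Numerical choices and degenerate inputs

- All indices 0-based, windows half-open; annotation files store
  integer sample indices with `fs` in a comment header.
- Zero-norm template columns raise a rank error in the public scaling
  operation; row-truncated beats use a partial solver that pins the
  coefficients of empty sections to 0 (they multiply an all-zero
  column).
- Metrics with zero denominators raise in `compute_metrics`; the
  report-level `evaluate_record` converts them to NaN so a record with
  no detections still produces a report.
- Signal CSVs round-trip exactly (`repr` on write, round-trip float
  parsing on read).
- Extraction refuses records shorter than 10 s; the detector refuses
  records shorter than 2 s (no threshold statistics).

## Problem sizes in the test and acceptance runs

Synthetic acceptance uses 120 s records (~160 maternal / ~280 fetal
beats) at 20, 10, 5 and 0 dB SNR; the optimizer-vs-closed-form check
uses 100 beats with additive noise of RMS 0.05 at 10 agents × 50
iterations; scaling recovery uses a 60 s noiseless maternal-only
source. End-to-end F1 comparisons across noise levels allow a
one-beat quantization slack (0.4 points at ~280 beats). The strict
noise-monotonicity check uses 20/5/0 dB: between 20 and 10 dB the
pipeline is saturated (differences of a single beat flip sign), while
the three chosen levels separate into distinct regimes (~99.5, ~98.5,
~90 % F1).

## Known limitations

- Fetal beats coinciding with a maternal QRS are partially absorbed by
  the template scaling; at default conditions this caps F1 around
  99.5 % rather than 100 %.
- The global averaged basis assumes morphology changes are captured by
  per-section scaling alone; beat-shape changes (e.g. ectopy) are not
  modelled.
- The kurtosis-based component selection assumes the fetal spikes are
  the heaviest-tailed residual feature; strong impulsive artifacts
  would be selected instead.
- WFDB loading requires the optional third-party `wfdb` package; CSV
  is the canonical interchange format.
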