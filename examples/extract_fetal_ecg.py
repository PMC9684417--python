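"""End-to-end fetal ECG extraction on a synthetic record.

Pipeline: preprocess -> PCA maternal reference -> maternal R-peaks ->
per-beat grey-wolf-optimised template subtraction on every channel ->
PCA enhancement of the residual -> fetal R-peak detection.  The
generator's ground truth lets us score the detections exactly.
"""

import numpy as np

from fecg_sagwo import (PipelineConfig, SynthConfig, compute_metrics,
                        extract_fecg, generate_record, ksqi, match_peaks)

record, truth = generate_record(SynthConfig(duration_s=120.0, seed=1))
result = extract_fecg(record, PipelineConfig(seed=1))

print(f"maternal beats cancelled: {len(result.mqrs)}")
print(f"fetal beats detected:     {len(result.fqrs)} "
      f"(truth: {len(truth.fetal_r)})")

tp, fp, fn = match_peaks(result.fqrs, truth.fetal_r)
stats = compute_metrics(tp, fp, fn).rounded()
print(f"TP={stats.tp} FP={stats.fp} FN={stats.fn}  "
      f"ACC={stats.acc}%  SE={stats.se}%  PPV={stats.ppv}%  F1={stats.f1}%")
print("-> F1 close to 100% means nearly every fetal R-peak was recovered "
      "within +-50 ms of the truth.")

gaps = np.array([(b.gwo_fitness - b.ls_fitness) / max(b.ls_fitness, 1e-12)
                 for b in result.per_beat])
print(f"per-beat optimizer excess over the closed-form optimum: "
      f"median {100 * np.median(gaps):.2f}% (0% would be the exact "
      f"least-squares scaling)")
print(f"kSQI of the extracted signal: {ksqi(result.fecg_signal):.1f} "
      "(> 5 indicates a clean, spike-dominated ECG)")
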