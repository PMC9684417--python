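"""The grey wolf optimizer on its own: a test function and a real beat.

Alpha, beta and delta — the best three solutions found so far — steer
every agent; the exploration coefficient decays linearly from 2 to 0,
shifting the pack from global search to local refinement.
"""

import numpy as np

from fecg_sagwo import GWOConfig, optimize
from fecg_sagwo.pipeline import PipelineConfig, optimize_beat_scaling
from fecg_sagwo.sequential_analysis import build_matrix, ls_scaling
from fecg_sagwo.synthetic_data import SynthConfig, generate_record

# 1. a 2-D quadratic with known minimum (1, -2)
cfg = GWOConfig([-5.0, -5.0], [5.0, 5.0], n_agents=10, max_iter=100, seed=0)
res = optimize(lambda x: float((x[0] - 1) ** 2 + (x[1] + 2) ** 2), cfg)
print(f"quadratic test: best position {res.best_position.round(4)} "
      f"(true minimizer [1, -2]), fitness {res.best_fitness:.2e}")
print(f"fitness history is non-increasing: "
      f"{bool(np.all(np.diff(res.fitness_history) <= 0))}")

# 2. a real per-beat scaling problem from the synthetic generator
_, truth = generate_record(SynthConfig(duration_s=30.0, seed=2))
matrix = build_matrix(truth.maternal_basis)
true_a = truth.true_scalings[3]
cycle = matrix @ true_a
a, mse = optimize_beat_scaling(matrix, cycle, PipelineConfig(max_iter=50),
                               np.random.default_rng(0))
ls_a = ls_scaling(matrix, cycle).as_array()
ls_mse = float(np.mean((cycle - matrix @ ls_a) ** 2))
print(f"\nbeat-scaling search: GWO found {a.as_array().round(4)}")
print(f"   closed-form (LS):  {ls_a.round(4)}")
print(f"   generator's truth: {true_a.round(4)}")
print(f"   GWO MSE {mse:.2e} vs LS optimum {ls_mse:.2e}")
print("-> on a noiseless beat the closed form recovers the drawn scaling "
      "exactly; the stochastic search lands within a sliver of the optimum "
      "(the weakly-observed P factor converges last).")
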