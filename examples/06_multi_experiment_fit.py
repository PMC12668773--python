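"""Multi-experiment fitting with a shared parameter.

Two experiments observe exponential decay from different initial
amounts (1.0 and 2.0) with 1% noise.  Both share the same decay
constant k.  Fitting them jointly through a shared-parameter map pools
the information and is typically more accurate than the worse of the
two independent fits.
"""

import numpy as np

import kinlearn as kl
from kinlearn.fitting import Dataset, ExperimentSpec, SharedParameterMap

rng = np.random.default_rng(4)
k_true = 1.0
times = np.linspace(0.5, 3.0, 6)


def make_dataset(s0):
    values = s0 * np.exp(-k_true * times) * (1 + 0.01 * rng.standard_normal(6))
    return Dataset.time_series(times, ["S"] * 6, values)


exp1 = ExperimentSpec(kl.decay_model(s0=1.0), make_dataset(1.0))
exp2 = ExperimentSpec(kl.decay_model(s0=2.0), make_dataset(2.0))
bounds = [(0.1, 5.0)]

for label, specs, pmap in [
    ("experiment 1 alone", [exp1], SharedParameterMap(["k"], [{"k": "k"}])),
    ("experiment 2 alone", [exp2], SharedParameterMap(["k"], [{"k": "k"}])),
    ("joint (shared k)", [exp1, exp2],
     SharedParameterMap(["k"], [{"k": "k"}, {"k": "k"}])),
]:
    result = kl.fit(specs, pmap, np.array([2.0]), bounds=bounds)
    print(f"{label:<20} k_hat = {result.global_vector[0]:.4f} "
          f"(error {abs(result.global_vector[0] - k_true):.4f}, "
          f"objective {result.objective:.2e})")

print(f"\ntrue k = {k_true}; the joint fit pools 12 observations and its "
      "error is usually below the worse single-experiment fit.")
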