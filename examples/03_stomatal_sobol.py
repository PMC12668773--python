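"""Time-resolved global sensitivity analysis of stomatal conductance.

The three-ODE stomatal model is driven by two 5-minute light pulses at
intensity 500 separated by dark phases.  The four relaxation time
constants get Gaussian priors (3 sigma = 20% of the default value) and
a radial Sobol design attributes the variance of the conductance gs to
the parameters, separately at every time point.

Expected pattern: the signal-rise constant tau_i matters only while a
pulse is on; in dark phases its total-order index is the smallest of
the four, and at pulse onset the water/osmotic constants dominate.
"""

import numpy as np

import kinlearn as kl

model = kl.kirschbaum_style_model()
priors = kl.case_study_1_priors(model)
protocol = kl.default_light_protocol()

result = kl.sobol_time_resolved(
    model, priors, n_base=64, seed=7, output="gs", protocol=protocol,
    points_per_segment=20, scheme="sobol",
)

t = np.array(result.output_labels)


def window_mean(a, b):
    sel = (t > a) & (t <= b)
    return np.nanmean(result.ST[sel], axis=0)


print(f"{'window':<22}" + "".join(f"{n:>9}" for n in result.names))
for label, (a, b) in [
    ("pulse 1 (15-20 min)", (15, 20)),
    ("dark    (20-30 min)", (20.5, 30)),
    ("pulse 2 (30-35 min)", (30, 35)),
    ("dark    (35-45 min)", (35.5, 45)),
]:
    means = window_mean(a, b)
    print(f"{label:<22}" + "".join(f"{m:9.3f}" for m in means))

print("\nTotal-order indices (mean per window). tau_i is non-negligible "
      "during the pulses but smallest in the dark windows; tau_w and "
      "tau_pi carry the variance at pulse onset.")
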