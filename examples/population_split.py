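"""Resolve slow and fast diffusivity populations.

High-cholesterol bilayers show spot-to-spot diffusivities drawn from two
populations (slow S and fast F regions).  This example draws 40 samples
per region — means 1.0 and 3.0 um^2/s, the scale of published confocal
measurements — fits a two-component Gaussian mixture on log10(D) by EM,
and scores the separation with Ashman's D (> 2 means cleanly bimodal).
"""

import numpy as np

from spotvar import DiffusivitySample, fit_two_component

rng = np.random.default_rng(7)
samples = [
    DiffusivitySample(float(10 ** (np.log10(mu) + 0.05 * rng.standard_normal())),
                      region_hint=hint)
    for mu, hint in [(1.0, "I")] * 40 + [(3.0, "II")] * 40
]

split = fit_two_component(samples)
mS, mF = split.means_linear
print(f"component S (slow): mean D = {mS:.2f} um^2/s, weight {split.weights[0]:.2f}")
print(f"component F (fast): mean D = {mF:.2f} um^2/s, weight {split.weights[1]:.2f}")
print(f"Ashman's D = {split.bimodality:.1f} (> 2 -> bimodal)")

truth = np.array([0] * 40 + [1] * 40)
err = np.mean(split.assignments != truth)
print(f"misassigned samples vs generating regions: {min(err, 1 - err):.1%}")
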