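"""Greedy change-point segmentation of a force curve.

Builds a noisy piecewise-affine signal with three planted discontinuities,
segments it with the greedy least-squares algorithm and shows the detected
breakpoints and the error trajectory.
"""

import numpy as np

from forcemap import ForceCurve, evaluate_piecewise, segment_curve

rng = np.random.default_rng(0)
n = 600
z = np.arange(n, dtype=float)
kinks = [150, 300, 450]
pieces = [(0.0, 0.001), (0.8, -0.003), (-0.4, 0.002), (0.5, 0.0)]
F = np.zeros(n)
bounds = [0] + kinks + [n]
for (level, slope), (a, b) in zip(pieces, zip(bounds[:-1], bounds[1:])):
    F[a:b] = level + slope * (z[a:b] - z[a])
F += rng.normal(0, 0.02, n)

curve = ForceCurve(z=z, F=F)
seg = segment_curve(curve, r=1, k_max=20, eps=0.02 ** 2)

print(f"planted discontinuities: {kinks}")
print(f"detected breakpoints:    {seg.breakpoints}")
print(f"stop reason: {seg.stop_reason} after {len(seg.breakpoints)} insertions")
print("mean squared error after each insertion (nN^2):")
print("  " + " -> ".join(f"{m:.2e}" for m in seg.mse_history))
smooth = evaluate_piecewise(seg, curve)
print(f"smoothed-curve residual SD: {np.std(curve.F - smooth):.4f} nN "
      f"(injected noise 0.02 nN)")
print()
print("the stopping rule halts once the global MSE reaches the empirical")
print("noise variance, so the piecewise fit tracks structure, not noise.")
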