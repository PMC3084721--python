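"""Fit a single AFM approach curve: electrostatics + Hertz + Hooke.

Simulates one approach curve over a bacterium-like surface (exponential
double-layer repulsion before contact, quadratic Hertz indentation, then a
linear cell-spring regime), runs the full fitting pipeline and compares the
recovered parameters with the generating truth.
"""

from forcemap import ApproachTruth, process_approach, simulate_approach_curve

truth = ApproachTruth(
    Z1=-300.0,      # virtual pre-contact point, nm
    A=0.05,         # electrostatic prefactor (force at Z1), nN
    kappa=0.1,      # inverse Debye length -> kappa^-1 = 10 nm
    E=1e6,          # Young modulus, Pa (1 MPa, typical soft bacterium)
    k_cell=0.1,     # cell spring constant, N/m
    Delta1=50.0,    # Hertz -> Hooke transition indentation, nm
    noise_sd=0.01,  # force noise, nN
)
curve, _ = simulate_approach_curve(truth, n=2700, seed=42)
result = process_approach(curve)

print(f"status: {result.status}")
print(f"{'parameter':<12}{'fitted':>12}{'true':>12}")
rows = [
    ("Z1 [nm]", result.Z1, truth.Z1),
    ("A [nN]", result.A, truth.A),
    ("k^-1 [nm]", result.kappa_inv, 1 / truth.kappa),
    ("E [kPa]", result.E / 1e3, truth.E / 1e3),
    ("k_cell[N/m]", result.k_cell, truth.k_cell),
    ("Delta1 [nm]", result.Delta1, truth.Delta1),
]
for name, got, want in rows:
    print(f"{name:<12}{got:>12.4g}{want:>12.4g}")
print()
print("Z1 anchors the indentation coordinate; A and k^-1 characterise the")
print("electric double layer; E the non-linear wall deformation; k_cell the")
print("linear compression regime linked to turgor pressure.")
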