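"""Fit a retraction curve: FJC pulls and rupture statistics.

Simulates a retraction with three polysaccharide-like pulls that rupture at
150, 215 and 300 nm, then detects the pulling regions, fits each to the
Freely Jointed Chain model and prints the rupture statistics.
"""

from forcemap import (
    RetractTruth,
    process_retract,
    pull_from_rupture,
    rupture_statistics,
    simulate_retract_curve,
)

pulls = [
    pull_from_rupture(rupture_z=150.0, rupture_force=0.15, lk=0.27, attach_z=110.0),
    pull_from_rupture(rupture_z=215.0, rupture_force=0.20, lk=0.27, attach_z=160.0),
    pull_from_rupture(rupture_z=300.0, rupture_force=0.30, lk=0.27, attach_z=225.0),
]
truth = RetractTruth(Zc=0.0, pulls=pulls, noise_sd=0.005)
curve, _ = simulate_retract_curve(truth, seed=5)
result = process_retract(curve, Zc=0.0)

print(f"status: {result.status}, regions: {len(result.regions)}")
print(f"{'region':<8}{'Lc [nm]':>10}{'lk [nm]':>10}{'N=Lc/lk':>10}{'F_rup [nN]':>12}")
for i, (fit, pull) in enumerate(zip(result.regions, pulls)):
    print(f"{i:<8}{fit.Lc:>10.1f}{fit.lk:>10.3f}{fit.N:>10.0f}{fit.F_rupture:>12.3f}"
          f"   (true Lc {pull[0]:.1f})")

deltaL, n_rupt, last_F, last_d = rupture_statistics(result)
print()
print(f"ruptures: {n_rupt} (regions + 1)")
print(f"deltaL between consecutive ruptures: {[round(d, 1) for d in deltaL]} nm")
print(f"last adhesion force {last_F:.3f} nN at distance {last_d:.1f} nm")
print()
print("Lc is the chain contour length, lk the Kuhn segment length; deltaL")
print("maps the spacing of branch points along the uncoiled macromolecule.")
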