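# Methods

This note records the models implemented in `forcemap`, the estimators and
their numerical details, what the synthetic data generator does and does not
emulate, and the known limitations.  Everything quantitative stated here is
measured by the test suite or by `scripts/acceptance.py`; nothing is quoted
from elsewhere.

## Conventions and units

All lengths are in nm, forces in nN, stiffnesses in nN/nm (numerically equal
to N/m).  A modulus in nN/nm² equals 1 GPa; Young moduli are reported in Pa.
Curves are stored with `z` ascending; probe-sample contact sits at the
largest `z` for approach curves and the smallest `z` for retraction curves.
Deflection data are converted to force by Hooke's law `F = k_c d` at parse
time.

Physical constants (Faraday, gas constant, vacuum permittivity, Boltzmann)
are fixed module-level values in `forcemap.constants`; `k_B T` at the
default 298.15 K is 4.116e-3 nN·nm.

## Pre-processing

1. Samples are sorted by `z` (stable sort; exact-duplicate `z` values are
   averaged into one sample so `z` is strictly increasing).
2. An affine baseline, fitted by ordinary least squares to `baseline_n`
   (default 500) samples at the far-from-contact end, is subtracted from
   `F`.  For curves shorter than the window, the window shrinks to `n/4`
   with a warning.  Because OLS residuals are orthogonal to the design, the
   operation is idempotent when the window is signal-free.
3. The noise variance is the unbiased sample variance of `F` over the first
   quarter of the curve at the non-contact end; it seeds the segmentation
   stopping rule and every noise-derived threshold (all are 3× the noise SD
   unless stated).

## Greedy change-point segmentation

A curve is partitioned at discontinuity indices into half-open intervals,
each smoothed by a degree-`r` polynomial (`r ∈ {0..3}`) fitted by least
squares about the interval midpoint.  Starting from a single interval, the
breakpoint whose insertion minimises the total squared error is added per
iteration (only the split interval is refitted); iteration stops at `k_max`
breakpoints or when `total SSE / n ≤ eps`.  Defaults follow the two use
cases: approach curves use `r = 2, k_max = 6, eps = 0` (a fixed number of
discontinuities); retraction curves use `r = 1, k_max = 20, eps = noise
variance`.

Numerical details:

- every interval keeps at least `r + 2` samples so SSE comparisons between
  degree-`r` fits stay meaningful;
- candidate scans use cumulative power sums accumulated from each
  interval's own endpoints, re-centred and rescaled per candidate before a
  batched normal-equations solve — O(n r²) per scan without the
  cancellation a global prefix-moment table would suffer; stored interval
  fits are always direct least-squares refits (asserted to agree with the
  scan to 1e-9);
- SSE below 1e-14 of the signal energy is rounding noise from an exact fit
  and is reported as exactly zero, which makes the `eps = 0` stopping rule
  reachable on noise-free piecewise-polynomial signals;
- ties between equally good candidates break towards the smallest index, so
  runs are bit-deterministic.

An exhaustive enumeration oracle (`n ≤ 300`, `k ≤ 2`) provides the
independent optimality check: the first greedy insertion coincides with the
global single-breakpoint optimum, and two greedy insertions stay within 5%
of the exhaustive two-breakpoint SSE on the tested signal family.

## Approach-curve analysis

**Region detection.**  The onset sample `z_c` is the last upward crossing
of a threshold `tau` by the smoothed signal (the raw-data variant is
available); `tau` defaults to 3× the noise SD, floored at 1e-3 of the peak
force so that the onset stays meaningful on nearly noise-free data — with a
vanishing threshold the crossing degenerates to the first sample, a case
that is explicitly treated as "no electrostatic region".  `Z0` and `Z1` are
the consecutive segmentation boundaries bracketing `z_c`; the following
boundary initialises the Hertz→Hooke edge.

**Anchor refinement.**  The prefactor `A` is the force extrapolated to the
anchor `Z1`, so an anchor error of one sample spacing `dz` aliases into `A`
by `exp(kappa dz)` (≈ 9% per nm-scale sample at `kappa^-1 = 10` nm), and
under noise the segmentation localises this edge only coarsely.  The anchor
is therefore refined by minimising the joint electrostatic-plus-contact
residual over candidates spanning 15 nm below to 30 nm above `z_c`, then
continuously (bounded Brent) between the best candidate's neighbours.  The
joint residual discriminates sharply: an anchor below the true edge leaves
a constant force mismatch across the entire contact region; one above it
misplaces the Hertz vertex.  Candidate contact fits are warm-started from
their predecessor so the objective varies smoothly with the anchor.

**Electrostatic fit.**  `J(A, kappa) = Σ (F_i - A e^{-kappa (Z1 - z_i)})²`
over the window below `Z1`; `A` is closed-form (clipped to `[0, A_max]`,
`A_max` defaulting to twice the window's peak force), `kappa` is scanned on
a 60-point log grid over `[1/200, 2] nm^-1` (Debye lengths 0.5–200 nm,
including the initial guess `P'/P` from the smoothed polynomial) and
refined by bounded Brent search.  Two refinements stabilise the estimate:

- the window is extended below the detected `Z0` to 6 Debye lengths below
  the anchor — the double-layer model holds where the force is merely
  unmeasurable, and the near-zero samples anchor the decay rate;
- the force zero is re-anchored on a signal-free reference window 50–250 nm
  below the fit window: the global affine baseline is extrapolated over a
  micron from its estimation window, and its error at the electrostatic
  region is comparable to weak prefactors (tens of pN).

A window with no positive force is the `A = 0` limit and is reported as
"no electrostatic region" while the mechanical fit proceeds.

**Contact fit.**  With `F1 = F(Z1)` (linear interpolation) and
`delta_i = (z_i - Z1) - (F_i - F1)/k_c`, the continuous model

```
M(delta) = F1                                          delta < delta0
M(delta) = F1 + a (delta - delta0)^2                   delta0..Delta1
M(delta) = F1 + a (Delta1 - delta0)^2 + k_cell (delta - Delta1)   above
```

is fitted under `0 ≤ delta0 ≤ Delta1 ≤ delta_max`, `a, k_cell ≥ 0`.  The
inner problem in `(a, k_cell)` is non-negative least squares; the outer 2-D
search over `(delta0, Delta1)` is Nelder-Mead from `delta0 = 0` and the
segmentation-based `Delta1` initialisation (plus two fixed fallback
starts).  `E = a π (1 - ν²) / (2 tan α)`; `Delta1` at the top of the range
flags `k_cell` as unreliable (no Hooke regime entered).  Samples below
`delta0` are modelled as the constant `F1` by default; a flag excludes them
instead.

## Retraction-curve analysis

**Regions of interest.**  Candidate pulls are the maximal spans where each
interval's polynomial decreases (quadratic intervals are split at the
vertex).  A span counts only if its fitted drop exceeds the noise
tolerance — otherwise flat noise intervals whose fitted slope happens to be
slightly negative masquerade as pulls.  Contiguous decreasing spans are
merged when the polynomial jump at the junction is below the same
tolerance; an upward jump above it is a rupture and always separates
regions (a convex FJC pull is otherwise approximated by several contiguous
decreasing affine pieces, which would split one physical pull into several
regions).  Regions are then dropped when they touch the skip zone (first
`skip_nm = 100` nm past the contact point, where non-specific detachment
makes the data uninterpretable), hold fewer than `min_region_pts = 5`
samples, or contain any non-negative force sample.

**Contact point.**  Taken from the paired approach fit (`Z1`) when one
exists; for retraction-only data it is the point where the smoothed
repulsive branch, followed outward from the minimum-z end, first drops
below 3× the noise SD (a literal zero crossing is a coin flip inside the
noise-flat gap that follows the wall).

**FJC fit.**  Per region, `Σ ((z_i - Zc) - Lc g(|F_i|; lk))²` with `g` the
Langevin factor; the cost is quadratic in `Lc` (closed-form, projected onto
`Lc ≥ z_b - Zc`), and `lk` is scanned on a log grid over `[1e-3, 5]` nm —
including the small initial value 0.01 nm that sits in the steep, convex
part of the 1-D cost — then Brent-refined.  `g(u)` uses the series `u/3`
below `u = 1e-4`.  Rupture position is the region's last sample; `deltaL`
is the spacing of consecutive rupture positions; the rupture count is the
number of regions plus one (the final full detachment).

## Whole-image processing

Pixels are processed sequentially and independently with one shared
configuration; a sub-grid therefore reproduces the full grid's values
exactly, and re-runs are bit-identical.  Approach images yield maps of
topography (`max(Z1) - Z1` over valid pixels), `A`, `kappa^-1`, `E` and
`k_cell`; retraction images yield maps of the last adhesion force and last
rupture distance (zero where nothing was detected — polymers absent or not
detectable) and pooled histograms of `Lc`, `lk`, `N`, `deltaL`, adhesion
force and rupture count.  Histogram bins are Freedman-Diaconis by default
with fallbacks for degenerate data; failed pixels are masked, never fatal.

## Synthetic data

The generator forward-evaluates the same models the fitters invert, plus an
affine baseline and i.i.d. Gaussian force noise (seeded; z positions are
noise-free).  Approach curves place the contact branch by inverting
`z = Z1 + delta + (F - F1)/k_c` with bracketed root finding (1e-12 nm
tolerance); the z-grid is shifted by less than half a spacing so `Z1` falls
exactly on a sample, making noise-free ground truth for the anchor-sensitive
`A` well defined.  Retraction curves superpose FJC pulls (force from a
monotone root-find of the extension law), each ending in a rupture jump,
plus a repulsive wall below `Zc` so the contact point is recoverable from
the retraction alone; `pull_from_rupture` builds pulls that rupture at a
prescribed position and force (realistic ruptures sit at 0.1–0.5 nN).

Default study conditions: 2700 samples per curve; approach curves span
~2.5 µm of piezo travel (`z` from −2000 to +500 nm around a contact at
−300 nm), noise SD 0.01 nN unless a test states otherwise; `A = 0.05` nN,
`kappa^-1 = 10` nm, `E = 1` MPa, `k_cell = 0.1` N/m, `Delta1 = 50` nm.
Image presets: `approach-demo` (8×8, dome-shaped `Z1` topography, uniform
mechanics, noise-free), `retract-annulus` (polymers on a ring, one
0.15 nN pull per ring pixel, noise 0.005 nN), `retract-bimodal` (two Kuhn
length populations, 0.07 and 0.27 nm).  Retraction presets use a 650 nm
span per curve since all planted pulls rupture below 300 nm.

Not emulated: instrument drift, hysteresis and virtual deflection; z noise
and quantisation; tip-shape convolution with sample curvature; correlated
(1/f) force noise; multiple simultaneous attachments with shared anchors.
Passing tests therefore demonstrate correctness of the estimators under the
stated noise model, not robustness to every instrumental artefact of real
data.

## Known limitations

- At force-noise SD 0.01 nN with `A = 0.05` nN and `kappa^-1 = 10` nm, the
  single-curve information content bounds the electrostatic parameters:
  even fitting with the true anchor and a generous window, median relative
  errors of `A` and `kappa^-1` sit near 10%, and the full pipeline (which
  must also estimate the anchor) measures ~13% medians over 100 replicates
  (see `scripts/acceptance.py`).  At noise SD 0.005 nN the direct fit is
  comfortably inside 10%.  The mechanical parameters are far better
  conditioned (medians ~2.5% for `E`, ~0.4% for `k_cell`).
- The FJC cost is measured in the extension coordinate (what makes it
  quadratic in `Lc`).  Force noise therefore passes through the non-linear
  Langevin factor and biases the fit — about −4% on `Lc` at noise SD
  0.01 nN for the canonical 312 nm chain, shrinking as the noise variance.
  A force-residual or variance-weighted fit would remove this bias but is a
  different estimator and is out of scope.
- Greedy segmentation is not globally optimal for `k ≥ 2`; the exhaustive
  oracle bounds the gap on small signals (≤ 5% in the tested family), but
  pathological signals can in principle do worse.
- With rupture forces only a few times the noise SD, neighbouring pulls can
  merge or split at the detection stage; pooled image statistics absorb
  this, per-pixel counts on weak pulls should be read with care.
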