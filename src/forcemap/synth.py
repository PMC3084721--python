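"""Synthetic force curves and force-volume images with known ground truth.

Every fitting stage in the package is exercised against curves generated by
forward evaluation of the same physical models the fitters invert:

* approach: affine baseline + exponential electrostatic repulsion below the
  virtual pre-contact point Z1, and the continuous Hertz-Hooke contact model
  above it.  The contact branch is generated in the indentation coordinate
  and mapped back to piezo position by inverting
  ``z = Z1 + delta + (F - F1)/k_c`` (a monotone root-find);
* retraction: a repulsive wall below the contact point, plus a sawtooth of
  FJC pulls.  The pulling force at a given tip-sample separation solves the
  FJC extension law for the force (monotone root-find); each pull ends with
  a rupture jump back towards the baseline.

Additive Gaussian noise on the force (never on z) is the only stochastic
element; all randomness is seeded.  The approach z-grid is shifted by less
than half a sample spacing so that Z1 falls exactly on a sample, which makes
noise-free ground truth well defined for the anchor-sensitive prefactor A.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Tuple, Union

import numpy as np
from scipy.optimize import brentq

from .constants import NN_PER_NM2_TO_PA, thermal_energy
from .curves_io import ForceCurve, FVImage, InstrumentConfig
from .errors import ConfigError
from .retract_fit import fjc_extension, langevin_factor

__all__ = [
    "ApproachTruth",
    "RetractTruth",
    "fjc_force",
    "pull_from_rupture",
    "hertz_prefactor",
    "simulate_approach_curve",
    "simulate_retract_curve",
    "simulate_fvi",
    "PRESETS",
]


@dataclass
class ApproachTruth:
    """Generating parameters of a synthetic approach curve."""

    Z1: float = -300.0        # virtual pre-contact point, nm
    A: float = 0.05           # electrostatic prefactor, nN
    kappa: float = 0.1        # inverse Debye length, 1/nm (kappa^-1 = 10 nm)
    E: float = 1e6            # Young modulus, Pa
    k_cell: float = 0.1       # cell spring constant, N/m
    delta0: float = 0.0       # virtual contact offset, nm
    Delta1: float = 50.0      # Hertz -> Hooke transition indentation, nm
    noise_sd: float = 0.01    # force noise SD, nN
    baseline: Tuple[float, float] = (0.0, 0.0)  # (intercept nN, slope nN/nm)


@dataclass
class RetractTruth:
    """Generating parameters of a synthetic retraction curve.

    ``pulls`` is a list of ``(Lc, lk, rupture_force, attach_z)`` tuples in
    (nm, nm, nN, nm), ordered by rupture position.  ``contact_stiffness``
    adds a repulsive wall below Zc so the contact point is recoverable from
    the retraction curve alone.
    """

    Zc: float = 0.0
    pulls: List[Tuple[float, float, float, float]] = field(default_factory=list)
    noise_sd: float = 0.01
    T: float = 298.15
    contact_stiffness: float = 0.05  # nN/nm


def hertz_prefactor(E_pa: float, nu: float = 0.5, alpha_deg: float = 35.0) -> float:
    """Hertz curvature a = 2 E tan(alpha) / (pi (1 - nu^2)) in nN/nm^2."""
    E = E_pa / NN_PER_NM2_TO_PA
    return 2.0 * E * math.tan(math.radians(alpha_deg)) / (math.pi * (1.0 - nu ** 2))


def pull_from_rupture(rupture_z: float, rupture_force: float, lk: float,
                      attach_z: float, Zc: float = 0.0, T: float = 298.15
                      ) -> Tuple[float, float, float, float]:
    """Build a pull tuple (Lc, lk, rupture_force, attach_z) that ruptures at
    a prescribed position.

    The contour length follows from the FJC law: the chain extension at the
    rupture force must equal ``rupture_z - Zc``, so
    ``Lc = (rupture_z - Zc) / g(u_rup)``.  Typical single-molecule ruptures
    sit at 0.1-0.5 nN.
    """
    if rupture_z <= Zc:
        raise ConfigError("rupture position must lie beyond the contact point")
    if rupture_force <= 0 or lk <= 0:
        raise ConfigError("rupture force and Kuhn length must be positive")
    u = rupture_force * lk / thermal_energy(T)
    g = float(langevin_factor(u))
    if g <= 0:
        raise ConfigError("rupture force too small for a finite contour length")
    Lc = (rupture_z - Zc) / g
    return (Lc, lk, rupture_force, attach_z)


def fjc_force(x: float, Lc: float, lk: float, T: float = 298.15) -> float:
    """Inverse FJC law: pulling force (nN) producing extension ``x`` (nm).

    Solved by bracketed root finding on the reduced force u = F lk / kB T;
    requires ``0 < x < Lc``.
    """
    if not 0 < x < Lc:
        raise ConfigError(f"extension must lie in (0, Lc); got x={x}, Lc={Lc}")
    ratio = x / Lc
    u_hi = max(3.0, 2.0 / (1.0 - ratio))
    u = brentq(lambda uu: langevin_factor(uu) - ratio, 1e-12, u_hi,
               xtol=1e-14, rtol=1e-14)
    return u * thermal_energy(T) / lk


# ---------------------------------------------------------------------------
# approach curves
# ---------------------------------------------------------------------------

def _contact_force_excess(delta, a, delta0, Delta1, k_cell):
    """Force above F1 in the continuous Hertz-Hooke model (delta in nm)."""
    d = np.clip(delta, delta0, Delta1) - delta0
    return a * d ** 2 + k_cell * np.maximum(delta - Delta1, 0.0)


def simulate_approach_curve(truth: ApproachTruth, n: int = 2700,
                            z_range: Tuple[float, float] = (-2000.0, 500.0),
                            seed: int = 0,
                            config: InstrumentConfig | None = None
                            ) -> Tuple[ForceCurve, ApproachTruth]:
    """Forward-simulate one approach curve from known parameters.

    ``z_range`` must contain Z1 strictly; ``n >= 500`` so the baseline window
    stays signal-free.  Same seed, same bytes.
    """
    config = config or InstrumentConfig()
    z0, z1 = z_range
    if not z0 < truth.Z1 < z1:
        raise ConfigError("z_range must contain Z1 strictly")
    if n < 500:
        raise ConfigError("approach simulation needs n >= 500")
    z = np.linspace(z0, z1, n)
    # snap the grid so Z1 is exactly a sample (shift < half a spacing)
    i_near = int(np.argmin(np.abs(z - truth.Z1)))
    z = z + (truth.Z1 - z[i_near])

    a = hertz_prefactor(truth.E, config.nu, config.alpha)
    F1 = truth.A  # electrostatic force extrapolated to Z1 (continuity)
    F = np.empty(n)
    pre = z <= truth.Z1
    F[pre] = truth.A * np.exp(-truth.kappa * (truth.Z1 - z[pre]))

    def travel_mismatch(delta, target):
        return (delta + _contact_force_excess(delta, a, truth.delta0,
                                              truth.Delta1, truth.k_cell)
                / config.k_c - target)

    for i in np.nonzero(~pre)[0]:
        target = z[i] - truth.Z1
        delta = brentq(travel_mismatch, 0.0, target, args=(target,),
                       xtol=1e-12, rtol=1e-14)
        F[i] = F1 + _contact_force_excess(delta, a, truth.delta0,
                                          truth.Delta1, truth.k_cell)

    b0, b1 = truth.baseline
    F = F + b0 + b1 * z
    if truth.noise_sd > 0:
        rng = np.random.default_rng(seed)
        F = F + rng.normal(0.0, truth.noise_sd, size=n)
    curve = ForceCurve(z=z, F=F, direction="approach", k_c=config.k_c)
    return curve, truth


# ---------------------------------------------------------------------------
# retraction curves
# ---------------------------------------------------------------------------

def simulate_retract_curve(truth: RetractTruth, n: int = 2700,
                           z_range: Optional[Tuple[float, float]] = None,
                           seed: int = 0,
                           config: InstrumentConfig | None = None
                           ) -> Tuple[ForceCurve, RetractTruth]:
    """Forward-simulate one retraction curve (sawtooth of FJC pulls).

    Each pull contributes an adhesive (negative) force from its attachment
    position up to its rupture position ``Zc + x(rupture_force)``, after
    which the force jumps back towards the baseline.  Overlapping pulls
    superpose.  A repulsive wall of stiffness ``contact_stiffness`` acts
    below Zc.
    """
    config = config or InstrumentConfig()
    if z_range is None:
        z_range = (truth.Zc - 50.0, truth.Zc + 2100.0)
    z0, z1 = z_range
    if not z0 <= truth.Zc < z1:
        raise ConfigError("z_range must contain Zc")
    z = np.linspace(z0, z1, n)
    F = np.zeros(n)
    F += truth.contact_stiffness * np.maximum(truth.Zc - z, 0.0)

    kbt = thermal_energy(truth.T)
    last_rupture = -np.inf
    for Lc, lk, f_rup, attach_z in truth.pulls:
        if min(Lc, lk, f_rup) <= 0:
            raise ConfigError("pull parameters must be positive")
        x_rup = fjc_extension(f_rup, Lc, lk, truth.T)
        z_rup = truth.Zc + x_rup
        if not truth.Zc <= attach_z < z_rup:
            raise ConfigError(
                f"infeasible pull geometry: attach_z={attach_z}, rupture at {z_rup:.1f}")
        if z_rup <= last_rupture:
            raise ConfigError("pulls must be ordered by rupture position")
        last_rupture = z_rup
        active = (z >= attach_z) & (z <= z_rup)
        for i in np.nonzero(active)[0]:
            x = z[i] - truth.Zc
            if x <= 0:
                continue
            ratio = x / Lc
            u_hi = max(3.0, 2.0 / max(1.0 - ratio, 1e-12))
            u = brentq(lambda uu: langevin_factor(uu) - ratio, 1e-12, u_hi,
                       xtol=1e-12, rtol=1e-12)
            F[i] -= u * kbt / lk
    if truth.noise_sd > 0:
        rng = np.random.default_rng(seed)
        F = F + rng.normal(0.0, truth.noise_sd, size=n)
    curve = ForceCurve(z=z, F=F, direction="retract", k_c=config.k_c)
    return curve, truth


# ---------------------------------------------------------------------------
# whole-image presets
# ---------------------------------------------------------------------------

FieldSpec = Union[float, Callable[[int, int], float]]


def _eval_field(spec: FieldSpec, r: int, c: int) -> float:
    return spec(r, c) if callable(spec) else float(spec)


def _pixel_seed(seed: int, r: int, c: int) -> int:
    # stable per-pixel stream, below 2**31
    ss = np.random.SeedSequence([int(seed), int(r), int(c)])
    return int(ss.generate_state(1)[0] % (2 ** 31 - 1))


def _dome(H: int, W: int) -> Callable[[int, int], float]:
    rc, cc = (H - 1) / 2.0, (W - 1) / 2.0
    sigma = max(min(H, W) / 4.0, 1.0)
    return lambda r, c: math.exp(-((r - rc) ** 2 + (c - cc) ** 2) / (2 * sigma ** 2))


def _annulus_mask(H: int, W: int, r_in: float = 2.0, r_out: float = 3.3) -> np.ndarray:
    rc, cc = (H - 1) / 2.0, (W - 1) / 2.0
    rr, cc_ = np.meshgrid(np.arange(H), np.arange(W), indexing="ij")
    d = np.hypot(rr - rc, cc_ - cc)
    return (d >= r_in) & (d <= r_out)


def _preset_approach_demo(shape, fields, seed, noise_sd, n, config):
    H, W = shape
    dome = _dome(H, W)
    f: Dict[str, FieldSpec] = {
        "Z1": lambda r, c: -500.0 + 200.0 * dome(r, c),
        "A": 0.05, "kappa": 0.1, "E": 1e6, "k_cell": 0.1,
        "delta0": 0.0, "Delta1": 50.0,
    }
    f.update(fields or {})
    sd = 0.0 if noise_sd is None else noise_sd
    approach = FVImage.empty_grid(H, W)
    truth_maps = {k: np.zeros((H, W)) for k in
                  ("Z1", "A", "kappa_inv", "E", "k_cell", "topography")}
    for r in range(H):
        for c in range(W):
            t = ApproachTruth(
                Z1=_eval_field(f["Z1"], r, c), A=_eval_field(f["A"], r, c),
                kappa=_eval_field(f["kappa"], r, c), E=_eval_field(f["E"], r, c),
                k_cell=_eval_field(f["k_cell"], r, c),
                delta0=_eval_field(f["delta0"], r, c),
                Delta1=_eval_field(f["Delta1"], r, c), noise_sd=sd)
            z_lo = t.Z1 - 1700.0
            curve, _ = simulate_approach_curve(
                t, n=n, z_range=(z_lo, t.Z1 + 800.0),
                seed=_pixel_seed(seed, r, c), config=config)
            curve.pixel = (r, c)
            approach[r][c] = curve
            truth_maps["Z1"][r, c] = t.Z1
            truth_maps["A"][r, c] = t.A
            truth_maps["kappa_inv"][r, c] = 1.0 / t.kappa
            truth_maps["E"][r, c] = t.E
            truth_maps["k_cell"][r, c] = t.k_cell
    truth_maps["topography"] = truth_maps["Z1"].max() - truth_maps["Z1"]
    fvi = FVImage(width=W, height=H, pixel_size=5000.0 / max(W, 1),
                  approach=approach, retract=FVImage.empty_grid(H, W),
                  config=config)
    return fvi, truth_maps


def _retract_pixel(pulls, seed, noise_sd, n, config, T=298.15):
    t = RetractTruth(Zc=0.0, pulls=pulls, noise_sd=noise_sd, T=T)
    curve, _ = simulate_retract_curve(t, n=n, z_range=(-50.0, 600.0),
                                      seed=seed, config=config)
    return curve


def _preset_retract_annulus(shape, fields, seed, noise_sd, n, config):
    H, W = shape
    mask = _annulus_mask(H, W)
    sd = 0.005 if noise_sd is None else noise_sd
    f_rup = 0.15
    pulls_on = [pull_from_rupture(250.0, f_rup, 0.27, 160.0)]
    retract = FVImage.empty_grid(H, W)
    truth_maps = {
        "last_adhesion_force": np.where(mask, f_rup, 0.0),
        "last_rupture_distance": np.where(mask, 250.0, 0.0),
        "annulus_mask": mask.astype(float),
    }
    for r in range(H):
        for c in range(W):
            pulls = pulls_on if mask[r, c] else []
            curve = _retract_pixel(pulls, _pixel_seed(seed, r, c), sd, n, config)
            curve.pixel = (r, c)
            retract[r][c] = curve
    fvi = FVImage(width=W, height=H, pixel_size=5000.0 / max(W, 1),
                  approach=FVImage.empty_grid(H, W), retract=retract,
                  config=config)
    return fvi, truth_maps


def _preset_retract_bimodal(shape, fields, seed, noise_sd, n, config):
    """Two planted Kuhn-length populations (0.07 nm and 0.27 nm)."""
    H, W = shape
    sd = 0.005 if noise_sd is None else noise_sd
    lk_a, lk_b = 0.07, 0.27
    pulls_a = [pull_from_rupture(240.0, 0.30, lk_a, 150.0)]
    pulls_b = [pull_from_rupture(250.0, 0.15, lk_b, 160.0)]
    retract = FVImage.empty_grid(H, W)
    lk_truth = np.zeros((H, W))
    for r in range(H):
        for c in range(W):
            use_a = (r * W + c) % 2 == 0
            pulls = pulls_a if use_a else pulls_b
            lk_truth[r, c] = lk_a if use_a else lk_b
            curve = _retract_pixel(pulls, _pixel_seed(seed, r, c), sd, n, config)
            curve.pixel = (r, c)
            retract[r][c] = curve
    fvi = FVImage(width=W, height=H, pixel_size=5000.0 / max(W, 1),
                  approach=FVImage.empty_grid(H, W), retract=retract,
                  config=config)
    return fvi, {"lk": lk_truth}


PRESETS = {
    "approach-demo": _preset_approach_demo,
    "retract-annulus": _preset_retract_annulus,
    "retract-bimodal": _preset_retract_bimodal,
}


def simulate_fvi(shape: Tuple[int, int] = (8, 8),
                 fields: Optional[Dict[str, FieldSpec]] = None,
                 preset: str = "approach-demo", seed: int = 0,
                 noise_sd: Optional[float] = None, n: int = 2700,
                 config: InstrumentConfig | None = None
                 ) -> Tuple[FVImage, Dict[str, np.ndarray]]:
    """Generate a synthetic force-volume image plus its ground-truth maps.

    Presets: ``approach-demo`` (dome-shaped topography, uniform mechanics,
    noise-free by default), ``retract-annulus`` (polymers planted on a ring,
    adhesion zero elsewhere), ``retract-bimodal`` (two Kuhn-length
    populations).  ``fields`` overrides per-parameter constants or
    ``(row, col) -> value`` functions where the preset supports it.
    Fully reproducible from ``(preset, shape, seed)``.
    """
    if preset not in PRESETS:
        raise ConfigError(f"unknown preset {preset!r}; available: {sorted(PRESETS)}")
    H, W = shape
    if H <= 0 or W <= 0:
        raise ConfigError("shape must be positive")
    config = config or InstrumentConfig()
    return PRESETS[preset](shape, fields, seed, noise_sd, n, config)
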