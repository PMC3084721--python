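"""Physical-parameter extraction from segmented approach curves.

An approach force curve on a soft, charged sample shows three successive
regimes as the tip travels towards and into the surface (z increasing):

* an exponential electrostatic double-layer repulsion
  ``F(z) = A exp(-kappa (Z1 - z))`` for ``z < Z1``, where ``kappa^-1`` is the
  Debye length and ``A`` the force extrapolated to the virtual pre-contact
  point ``Z1``;
* a Hertzian (conical-indenter) regime ``F = F1 + a (delta - delta0)^2`` in
  the indentation coordinate ``delta``, giving the Young modulus through
  ``a = 2 E tan(alpha) / (pi (1 - nu^2))``;
* a linear Hooke regime of slope ``k_cell`` (the cell spring constant,
  related to turgor pressure) beyond the transition indentation ``Delta1``.

The piecewise model is continuous at ``delta0`` and ``Delta1``.  Both fits
exploit the parameters that enter linearly: the electrostatic cost is
quadratic in ``A`` (closed form with clipping to ``[0, A_max]``), leaving a
bounded 1-D search over ``kappa``; the contact cost is quadratic in
``(a, k_cell)`` (non-negative least squares), leaving a bounded 2-D search
over ``(delta0, Delta1)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np
from scipy import optimize

from . import constants
from .curves_io import ForceCurve, InstrumentConfig, estimate_noise_variance, preprocess_curve
from .errors import FitError
from .segmentation import SegmentationResult, evaluate_piecewise, segment_curve

__all__ = [
    "ApproachFitResult",
    "ElectrostaticRegion",
    "detect_electrostatic_region",
    "fit_electrostatic",
    "debye_length_theoretical",
    "compute_indentation",
    "fit_contact",
    "process_approach",
]

DEFAULT_KAPPA_BOUNDS = (1.0 / 200.0, 2.0)  # Debye lengths 0.5..200 nm
_KAPPA_FALLBACK = 0.1  # nm^-1, used when the polynomial ratio is unusable


class NoRepulsionError(FitError):
    """The electrostatic window holds no positive (repulsive) force."""


@dataclass
class ElectrostaticRegion:
    """Outcome of the region-of-interest detection on an approach curve."""

    status: str                      # "ok" or "no_electrostatic" / "no_contact"
    Z0: float = math.nan             # onset of measurable force, nm
    Z1: float = math.nan             # electrostatic -> Hertz edge, nm
    i0: int = -1                     # data index of Z0
    i1: int = -1                     # data index of Z1
    delta1_init_index: int = -1      # index used to initialise Delta1
    istar: int = -1                  # index of the onset sample z_c


@dataclass
class ApproachFitResult:
    """All parameters extracted from one approach curve.

    Units: Z0/Z1/delta0/Delta1 in nm, A in nN, kappa in 1/nm, E in Pa,
    k_cell in N/m, residuals in nN^2.
    """

    status: str = "skipped"
    Z0: float = math.nan
    Z1: float = math.nan
    A: float = math.nan
    kappa: float = math.nan
    delta0: float = math.nan
    Delta1: float = math.nan
    E: float = math.nan
    k_cell: float = math.nan
    sse_elec: float = math.nan
    sse_contact: float = math.nan
    k_cell_reliable: bool = True

    @property
    def kappa_inv(self) -> float:
        return 1.0 / self.kappa if self.kappa and self.kappa > 0 else math.nan

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in (
            "status", "Z0", "Z1", "A", "kappa", "delta0", "Delta1", "E",
            "k_cell", "sse_elec", "sse_contact", "k_cell_reliable")}
        d["kappa_inv"] = self.kappa_inv
        return d


# ---------------------------------------------------------------------------
# theoretical Debye length
# ---------------------------------------------------------------------------

def debye_length_theoretical(c_inf: float, T: float = 298.15,
                             eps_r: float = 78.5) -> float:
    """Debye length kappa^-1 (nm) of a symmetric monovalent electrolyte.

    ``kappa^-1 = sqrt(eps0 eps_r R T / (2 F^2 c))`` with the bulk
    concentration ``c_inf`` in mol/L (converted internally to mol/m^3).
    At 1 mM and room temperature this is ~9.6-9.8 nm depending on the
    constants adopted.
    """
    if c_inf <= 0:
        raise FitError("electrolyte concentration must be positive")
    c_m3 = c_inf * 1e3
    lam2 = (constants.VACUUM_PERMITTIVITY * eps_r * constants.GAS_CONSTANT * T
            / (2.0 * constants.FARADAY ** 2 * c_m3))
    return math.sqrt(lam2) * 1e9  # m -> nm


# ---------------------------------------------------------------------------
# region detection
# ---------------------------------------------------------------------------

def detect_electrostatic_region(curve: ForceCurve, seg: SegmentationResult,
                                tau: float, use_smoothed: bool = True
                                ) -> ElectrostaticRegion:
    """Locate the electrostatic region from the segmentation output.

    The onset sample ``z_c`` is the smallest ``z_i`` such that the force stays
    at or above the threshold ``tau`` for every ``j >= i`` (the last upward
    crossing of ``tau``); by default the test is applied to the
    piecewise-smoothed signal, ``use_smoothed=False`` applies it to the raw
    data.  ``Z0`` and ``Z1`` are the consecutive segmentation boundaries
    bracketing ``z_c`` (curve end points act as outer boundaries), and the
    boundary after ``Z1`` initialises the Hertz-to-Hooke edge; when there is
    none, the midpoint of the contact range is used.

    An onset at the very first sample is the pathological noise-free case and
    reports ``no_electrostatic``; an onset past the last breakpoint leaves no
    contact interval and reports ``no_contact``.
    """
    n = curve.n
    Fref = evaluate_piecewise(seg, curve) if use_smoothed else curve.F
    below = np.nonzero(Fref < tau)[0]
    if below.size == 0:
        istar = 0
    else:
        istar = int(below[-1]) + 1
    if istar == 0:
        return ElectrostaticRegion(status="no_electrostatic")
    if istar >= n:
        return ElectrostaticRegion(status="no_electrostatic")
    bounds = [0] + list(seg.breakpoints) + [n]
    j = int(np.searchsorted(np.asarray(bounds), istar, side="right")) - 1
    i0, i1 = bounds[j], bounds[j + 1]
    if i1 >= n:
        # z_c beyond the last breakpoint: no interval left for the contact fit
        return ElectrostaticRegion(status="no_contact", Z0=curve.z[i0],
                                   i0=i0, i1=-1)
    if j + 2 < len(bounds) and bounds[j + 2] < n:
        d1 = bounds[j + 2]
    else:
        d1 = (i1 + n) // 2  # midpoint of the contact range
    return ElectrostaticRegion(status="ok", Z0=float(curve.z[i0]),
                               Z1=float(curve.z[i1]), i0=i0, i1=i1,
                               delta1_init_index=d1, istar=istar)


# ---------------------------------------------------------------------------
# electrostatic fit
# ---------------------------------------------------------------------------

def _elec_profile(kappa, s, F, A_max):
    """Closed-form A (clipped to [0, A_max]) and cost for a given kappa."""
    e = np.exp(-kappa * s)
    denom = float(e @ e)
    A = float(F @ e) / denom if denom > 0 else 0.0
    A = min(max(A, 0.0), A_max)
    resid = F - A * e
    return A, float(resid @ resid)


def fit_electrostatic(curve: ForceCurve, Z0: float, Z1: float,
                      A_max: Optional[float] = None,
                      kappa_bounds: Tuple[float, float] = DEFAULT_KAPPA_BOUNDS,
                      kappa_init: Optional[float] = None,
                      local_offset: bool = True):
    """Fit ``F = A exp(-kappa (Z1 - z))`` on the window ``Z0 <= z < Z1``.

    The cost is quadratic in ``A`` so the inner solve is closed-form (clipped
    to ``[0, A_max]``); the outer problem is a bounded 1-D minimisation over
    ``kappa``, scanned on a log-spaced grid (including ``kappa_init``, the
    smoothed-polynomial ratio F'/F at Z1-) and refined by bounded Brent
    search.  Returns ``(A [nN], kappa [1/nm], sse [nN^2])``.

    With ``local_offset`` (default) the force zero is re-anchored on a
    signal-free reference window 50-250 nm below the fit window before
    fitting: the global affine baseline is estimated far from contact, and
    its extrapolation error at the electrostatic region is comparable to
    weak prefactors.  The correction is skipped when fewer than 30 reference
    samples exist.

    Raises :class:`FitError` when the window holds fewer than 5 samples or no
    positive force (no measurable repulsion).
    """
    lo, hi = kappa_bounds
    if not 0 < lo < hi:
        raise FitError("kappa bounds must satisfy 0 < lo < hi")
    mask = (curve.z >= Z0) & (curve.z < Z1)
    if int(mask.sum()) < 5:
        raise FitError("fewer than 5 samples in the electrostatic window")
    zw = curve.z[mask]
    Fw = curve.F[mask]
    if local_offset:
        ref = (curve.z >= Z0 - 250.0) & (curve.z < Z0 - 50.0)
        if int(ref.sum()) >= 30:
            Fw = Fw - float(curve.F[ref].mean())
    if not np.any(Fw > 0):
        raise NoRepulsionError("no positive force in the electrostatic window")
    if A_max is None:
        A_max = 2.0 * float(Fw.max())
    s = Z1 - zw  # decay coordinate, > 0
    if kappa_init is None or not np.isfinite(kappa_init) or kappa_init <= 0:
        kappa_init = _KAPPA_FALLBACK
    grid = np.geomspace(lo, hi, 60)
    ki = min(max(kappa_init, lo), hi)
    grid = np.unique(np.append(grid, ki))
    costs = np.array([_elec_profile(k, s, Fw, A_max)[1] for k in grid])
    ib = int(np.argmin(costs))
    blo = grid[max(ib - 1, 0)]
    bhi = grid[min(ib + 1, grid.size - 1)]
    if blo < bhi:
        res = optimize.minimize_scalar(
            lambda k: _elec_profile(k, s, Fw, A_max)[1],
            bounds=(blo, bhi), method="bounded",
            options={"xatol": 1e-10})
        kappa = float(res.x) if res.fun <= costs[ib] else float(grid[ib])
    else:
        kappa = float(grid[ib])
    A, sse = _elec_profile(kappa, s, Fw, A_max)
    return A, kappa, sse


# ---------------------------------------------------------------------------
# indentation and contact fit
# ---------------------------------------------------------------------------

def compute_indentation(curve: ForceCurve, Z1: float, k_c: float):
    """Indentation ``delta_i = (z_i - Z1) - (F_i - F(Z1)) / k_c`` for z >= Z1.

    ``F(Z1)`` is linearly interpolated between the two samples bracketing Z1.
    Returns ``(delta, F_contact, F1)`` with delta/force pairs sorted by
    increasing indentation.  Raises :class:`FitError` with fewer than 6
    contact samples.
    """
    mask = curve.z >= Z1
    if int(mask.sum()) < 6:
        raise FitError("fewer than 6 samples past the contact point")
    F1 = float(np.interp(Z1, curve.z, curve.F))
    zc = curve.z[mask]
    Fc = curve.F[mask]
    delta = (zc - Z1) - (Fc - F1) / k_c
    order = np.argsort(delta, kind="stable")
    return delta[order], Fc[order], F1


def _contact_design(delta, delta0, Delta1):
    """Basis functions of the continuous Hertz-Hooke model (force minus F1)."""
    phi_h = (np.clip(delta, delta0, Delta1) - delta0) ** 2
    phi_l = np.maximum(delta - Delta1, 0.0)
    return phi_h, phi_l


def _contact_cost(params, delta, y, include_precontact):
    delta0, Delta1 = params
    dmax = delta[-1]
    if not (0.0 <= delta0 <= Delta1 <= dmax):
        return np.inf, (0.0, 0.0)
    if include_precontact:
        d, yy = delta, y
    else:
        keep = delta >= delta0
        if int(keep.sum()) < 4:
            return np.inf, (0.0, 0.0)
        d, yy = delta[keep], y[keep]
    phi_h, phi_l = _contact_design(d, delta0, Delta1)
    X = np.column_stack([phi_h, phi_l])
    coef, rnorm = optimize.nnls(X, yy)
    return rnorm ** 2, (float(coef[0]), float(coef[1]))


def fit_contact(delta, F, F1: float, Delta1_init: float,
                config: InstrumentConfig, include_precontact: bool = True,
                n_starts: int = 3, extra_starts=None):
    """Constrained LS fit of the continuous Hertz-Hooke contact model.

    Model (forces in nN, indentation in nm)::

        M(delta) = F1                                          delta <  delta0
        M(delta) = F1 + a (delta - delta0)^2                   delta0 <= delta <= Delta1
        M(delta) = F1 + a (Delta1 - delta0)^2
                      + k_cell (delta - Delta1)                delta >  Delta1

    subject to ``0 <= delta0 <= Delta1 <= delta_max``, ``a >= 0`` and
    ``k_cell >= 0``.  The inner problem in ``(a, k_cell)`` is solved by
    non-negative least squares; the outer 2-D search over
    ``(delta0, Delta1)`` runs Nelder-Mead from the initialisations
    ``delta0 = 0`` and ``Delta1 = Delta1_init`` (plus two fixed fallback
    starts), deterministically.

    ``include_precontact=False`` drops samples with ``delta < delta0`` from
    the residual instead of modelling them as the constant ``F1``.

    Returns ``(E [Pa], k_cell [N/m], delta0, Delta1, sse, k_cell_reliable)``.
    The Hertz curvature ``a`` converts to the Young modulus via
    ``E = a pi (1 - nu^2) / (2 tan alpha)``.
    """
    delta = np.asarray(delta, dtype=float)
    F = np.asarray(F, dtype=float)
    if delta.size < 6:
        raise FitError("contact fit needs at least 6 samples")
    y = F - F1
    dmax = float(delta[-1])
    Delta1_init = min(max(Delta1_init, 0.0), dmax)

    def cost(p):
        return _contact_cost(p, delta, y, include_precontact)[0]

    starts = [(0.0, Delta1_init), (0.0, 0.5 * dmax), (0.0, 0.9 * dmax)][:max(n_starts, 1)]
    for s in (extra_starts or []):
        starts.append((min(max(s[0], 0.0), dmax), min(max(s[1], 0.0), dmax)))
    best = None
    for x0 in starts:
        res = optimize.minimize(
            cost, x0=np.array(x0), method="Nelder-Mead",
            bounds=[(0.0, dmax), (0.0, dmax)],
            options={"xatol": 1e-6, "fatol": 1e-14, "maxiter": 400})
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun):
        raise FitError("contact fit did not converge")
    delta0, Delta1 = float(best.x[0]), float(best.x[1])
    if Delta1 < delta0:
        delta0, Delta1 = Delta1, delta0
    sse, (a, k_cell) = _contact_cost((delta0, Delta1), delta, y, include_precontact)
    if not np.isfinite(sse):
        raise FitError("contact fit did not converge")
    alpha_rad = math.radians(config.alpha)
    E_nn_nm2 = a * math.pi * (1.0 - config.nu ** 2) / (2.0 * math.tan(alpha_rad))
    E_pa = E_nn_nm2 * constants.NN_PER_NM2_TO_PA
    # Delta1 at the top of the range means the Hooke regime was never entered
    k_cell_reliable = Delta1 < dmax * (1.0 - 1e-6)
    return E_pa, float(k_cell), delta0, Delta1, float(sse), k_cell_reliable


# ---------------------------------------------------------------------------
# contact-point (Z1) refinement
# ---------------------------------------------------------------------------

def _joint_fit(pre: ForceCurve, Z0: float, Z1: float, z_d1: float,
               config: InstrumentConfig, kappa_bounds, kinit,
               include_precontact: bool, n_starts: int = 1,
               elec_span_debye: float = 6.0, extra_starts=None):
    """Electrostatic + contact fit for a candidate anchor Z1.

    The exponential is first fitted on the detected window ``[Z0, Z1)``; the
    window is then extended down to ``elec_span_debye`` Debye lengths below
    the anchor (the double-layer model still holds where the force is merely
    unmeasurable, and the extra near-zero samples stabilise the decay rate)
    and the fit repeated.  A window with no repulsive force is the A = 0
    limit: the electrostatic part is reported absent, with the flat-zero
    residual as its cost.  Returns (total_sse, elec_fit_or_None,
    contact_fit) or None if the candidate leaves either window too short.
    """
    Z0_eff = min(Z0, Z1 - 30.0)  # pilot window never narrower than 30 nm
    try:
        try:
            A, kappa, sse_e = fit_electrostatic(pre, Z0_eff, Z1,
                                                A_max=config.A_max,
                                                kappa_bounds=kappa_bounds,
                                                kappa_init=kinit)
            z_lo = Z1 - elec_span_debye / kappa
            if z_lo < Z0_eff:
                A, kappa, sse_e = fit_electrostatic(
                    pre, z_lo, Z1, A_max=config.A_max,
                    kappa_bounds=kappa_bounds, kappa_init=kappa)
            elec = (A, kappa, sse_e)
        except NoRepulsionError:
            mask = (pre.z >= Z0_eff) & (pre.z < Z1)
            Fw = pre.F[mask]
            elec = None
            sse_e = float(Fw @ Fw)
        delta, Fc, F1 = compute_indentation(pre, Z1, config.k_c)
        F_d1 = float(np.interp(z_d1, pre.z, pre.F))
        Delta1_init = (z_d1 - Z1) - (F_d1 - F1) / config.k_c
        contact = fit_contact(delta, Fc, F1, Delta1_init, config,
                              include_precontact=include_precontact,
                              n_starts=n_starts, extra_starts=extra_starts)
    except FitError:
        return None
    return sse_e + contact[4], elec, contact


def refine_contact_anchor(pre: ForceCurve, region: ElectrostaticRegion,
                          config: InstrumentConfig, kappa_bounds, kinit,
                          include_precontact: bool = True,
                          span_below: float = 15.0, span_above: float = 30.0,
                          max_candidates: int = 24) -> float:
    """Sub-breakpoint refinement of the virtual pre-contact point Z1.

    The electrostatic prefactor A is the force extrapolated to the anchor
    Z1, so an anchor off by one sample spacing already aliases into A by a
    factor exp(kappa * dz), and under noise the segmentation localises the
    electrostatic-to-Hertz edge only coarsely.  The anchor is therefore
    refined by minimising the joint residual of the electrostatic and
    contact fits over candidates spanning ``span_below`` nm below to
    ``span_above`` nm above the onset sample z_c, followed by a bounded
    continuous search between the best candidate's neighbours.  The joint
    residual discriminates sharply: an anchor below the true edge leaves a
    constant force mismatch across the whole contact region, one above
    misplaces the Hertz vertex.
    """
    z = pre.z
    n = pre.n
    dz = float(np.median(np.diff(z)))
    center = region.istar if region.istar >= 0 else region.i1
    lo = max(center - int(round(span_below / max(dz, 1e-9))), 5)
    hi_cap = region.delta1_init_index - 1 if region.delta1_init_index > 0 else n - 7
    hi = min(center + int(round(span_above / max(dz, 1e-9))), hi_cap, n - 7)
    if hi <= lo:
        return region.Z1
    step = max(1, (hi - lo) // max_candidates)
    z_d1 = z[region.delta1_init_index] if 0 <= region.delta1_init_index < n \
        else z[-1]

    # scan candidates, warm-starting each contact fit from its predecessor so
    # the objective varies smoothly with the anchor (no optimizer jitter)
    warm = {"start": None}

    def cost(zc):
        extra = [warm["start"]] if warm["start"] is not None else None
        out = _joint_fit(pre, region.Z0, float(zc), z_d1, config,
                         kappa_bounds, kinit, include_precontact,
                         extra_starts=extra)
        if out is None:
            return np.inf
        warm["start"] = (out[2][2], out[2][3])  # (delta0, Delta1)
        return out[0]

    cands = [(cost(float(z[i])), float(z[i])) for i in range(lo, hi + 1, step)]
    cands = [c for c in cands if np.isfinite(c[0])]
    if not cands:
        return region.Z1
    best_sse, best_z = min(cands)
    order = sorted(zc for _s, zc in cands)
    k = order.index(best_z)
    blo = order[max(k - 1, 0)]
    bhi = order[min(k + 1, len(order) - 1)]
    if blo < bhi:
        res = optimize.minimize_scalar(cost, bounds=(blo, bhi),
                                       method="bounded",
                                       options={"xatol": 1e-3})
        if np.isfinite(res.fun) and res.fun <= best_sse:
            best_z = float(res.x)
    return best_z


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

def _kappa_init_from_segmentation(seg: SegmentationResult, i1: int, Z1: float):
    """Ratio F'/F of the smoothed polynomial just below Z1 (kappa heuristic)."""
    for iv in seg.intervals:
        if iv.stop == i1:
            val = float(iv(Z1))
            der = float(iv.derivative(Z1))
            if val > 0 and der > 0:
                return der / val
            return None
    return None


def process_approach(curve: ForceCurve, config: InstrumentConfig | None = None,
                     r: int = 2, k_max: int = 6, eps: float = 0.0,
                     tau: Optional[float] = None,
                     kappa_bounds: Tuple[float, float] = DEFAULT_KAPPA_BOUNDS,
                     include_precontact: bool = True,
                     use_smoothed_onset: bool = True,
                     refine_z1: bool = True,
                     tau_floor_frac: float = 1e-3) -> ApproachFitResult:
    """Full approach-curve pipeline: preprocess, segment, detect, fit.

    Segmentation defaults to degree 2 with 6 discontinuity points (approach
    curves are well approximated by affine and quadratic pieces).  The onset
    threshold ``tau`` defaults to three times the noise standard deviation
    estimated on the flat part of the curve, floored at ``tau_floor_frac``
    times the largest force so the onset stays meaningful on nearly
    noise-free data.  After the breakpoint-level detection, the anchor Z1 is
    refined to sub-sample precision by minimising the joint
    electrostatic-plus-contact residual (``refine_z1=False`` keeps the raw
    breakpoint).  Partial failures degrade the ``status`` field
    ("no_electrostatic", "no_contact"); no exception leaks from
    physics-level failures.
    """
    config = config or InstrumentConfig()
    pre = preprocess_curve(curve, config)
    noise_var = estimate_noise_variance(pre)
    if tau is None:
        tau = max(3.0 * math.sqrt(noise_var),
                  tau_floor_frac * float(pre.F.max(initial=0.0)))
    seg = segment_curve(pre, r=r, k_max=k_max, eps=eps)
    region = detect_electrostatic_region(pre, seg, tau,
                                         use_smoothed=use_smoothed_onset)
    if region.status != "ok":
        return ApproachFitResult(status=region.status, Z0=region.Z0)
    kinit = _kappa_init_from_segmentation(seg, region.i1, region.Z1)
    Z1 = region.Z1
    if refine_z1:
        Z1 = refine_contact_anchor(pre, region, config, kappa_bounds, kinit,
                                   include_precontact=include_precontact)
    result = ApproachFitResult(status="ok", Z0=region.Z0, Z1=Z1)
    di = region.delta1_init_index
    z_d1 = pre.z[di] if 0 <= di < pre.n else pre.z[-1]
    out = _joint_fit(pre, region.Z0, Z1, z_d1, config, kappa_bounds, kinit,
                     include_precontact, n_starts=3)
    if out is None:
        # fall back to whichever half still works so the status is informative
        try:
            A, kappa, sse_e = fit_electrostatic(pre, region.Z0, Z1,
                                                A_max=config.A_max,
                                                kappa_bounds=kappa_bounds,
                                                kappa_init=kinit)
            result.A, result.kappa, result.sse_elec = A, kappa, sse_e
            result.status = "no_contact"
        except FitError:
            result.status = "no_electrostatic"
        return result
    _total, elec, (E, k_cell, d0, D1, sse_c, ok_kcell) = out
    if elec is None:
        result.status = "no_electrostatic"
    else:
        result.A, result.kappa, result.sse_elec = elec
    result.E, result.k_cell = E, k_cell
    result.delta0, result.Delta1 = d0, D1
    result.sse_contact = sse_c
    result.k_cell_reliable = ok_kcell
    return result
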