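"""FJC analysis of retraction force curves and rupture statistics.

During retraction, biopolymers attached to the tip are stretched and detach
in a sawtooth of adhesive (negative-force) pulls.  Each pull follows the
Freely Jointed Chain model: the extension of a chain of contour length
``Lc`` built from Kuhn segments of length ``lk`` under pulling force ``F``
is::

    x(F) = Lc * (coth(u) - 1/u),   u = F lk / (kB T)

The analysis segments the curve with piecewise affine smoothing, finds the
decreasing regions of the smoothed signal beyond the first ~100 nm from the
contact point, fits each region to the FJC model (residual measured in the
extension coordinate, which makes the cost quadratic in ``Lc``), and
assembles rupture statistics: the number of ruptures, the z-distance
``deltaL`` between consecutive rupture positions, and the force and distance
of the last adhesive event.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np
from scipy import optimize

from .constants import thermal_energy
from .curves_io import ForceCurve, InstrumentConfig, estimate_noise_variance, preprocess_curve
from .errors import FitError
from .segmentation import SegmentationResult, evaluate_piecewise, segment_curve

__all__ = [
    "FJCRegionFit",
    "RetractFitResult",
    "fjc_extension",
    "langevin_factor",
    "detect_regions",
    "fit_fjc_region",
    "process_retract",
    "rupture_statistics",
    "estimate_contact_point",
]

DEFAULT_LK_BOUNDS = (1e-3, 5.0)  # nm
DEFAULT_LK_INIT = 0.01           # nm; small start keeps the search in the
                                 # steep convex valley of the 1-D cost


def langevin_factor(u):
    """``coth(u) - 1/u`` with a series branch for small arguments.

    This is the bracketed factor of the FJC extension law; it rises from 0
    towards 1 as the pulling force saturates the chain.  For ``u < 1e-4`` the
    series ``u/3`` is used (next term is u^3/45, below double rounding here).
    """
    u = np.asarray(u, dtype=float)
    out = np.empty_like(u)
    small = u < 1e-4
    out[small] = u[small] / 3.0
    ub = u[~small]
    out[~small] = 1.0 / np.tanh(ub) - 1.0 / ub
    return out if out.ndim else float(out)


def fjc_extension(F_mag, Lc: float, lk: float, T: float = 298.15):
    """FJC extension (nm) at pulling force magnitude ``F_mag`` (nN).

    Strictly increasing in the force and bounded above by ``Lc``.
    Raises :class:`FitError` for non-positive force or parameters.
    """
    F_arr = np.asarray(F_mag, dtype=float)
    if np.any(F_arr <= 0):
        raise FitError("pulling force must be positive")
    if Lc <= 0 or lk <= 0:
        raise FitError("Lc and lk must be positive")
    u = F_arr * lk / thermal_energy(T)
    x = Lc * langevin_factor(u)
    return x if np.ndim(F_mag) else float(x)


# ---------------------------------------------------------------------------
# results
# ---------------------------------------------------------------------------

@dataclass
class FJCRegionFit:
    """FJC fit of one region of interest (one pull)."""

    z_a: float                   # region lower bound, nm
    z_b: float                   # region upper bound (rupture position), nm
    Lc: float                    # contour length, nm
    lk: float                    # Kuhn length, nm
    F_rupture: float             # force magnitude at z_b, nN
    sse: float                   # extension-residual SSE, nm^2
    n_pts: int

    @property
    def N(self) -> float:
        """Number of monomers, N = Lc / lk."""
        return self.Lc / self.lk


@dataclass
class RetractFitResult:
    status: str = "no_regions"   # ok / no_regions / excluded
    Zc: float = math.nan
    regions: List[FJCRegionFit] = field(default_factory=list)

    @property
    def n_ruptures(self) -> int:
        # convention: number of regions of interest + 1 (the final full
        # detachment counts as a rupture as well); zero when nothing detected
        return len(self.regions) + 1 if self.regions else 0

    @property
    def deltaL(self) -> List[float]:
        zb = [r.z_b for r in self.regions]
        return [b - a for a, b in zip(zb, zb[1:])]

    @property
    def last_adhesion_force(self) -> float:
        return self.regions[-1].F_rupture if self.regions else 0.0

    @property
    def last_rupture_distance(self) -> float:
        return self.regions[-1].z_b - self.Zc if self.regions else 0.0


def rupture_statistics(result: RetractFitResult):
    """(deltaL list, n_ruptures, last_adhesion_force, last_rupture_distance)."""
    return (result.deltaL, result.n_ruptures, result.last_adhesion_force,
            result.last_rupture_distance)


# ---------------------------------------------------------------------------
# region detection
# ---------------------------------------------------------------------------

def _decreasing_span(iv, z: np.ndarray) -> Optional[Tuple[int, int]]:
    """Maximal index sub-range of interval iv where its polynomial decreases."""
    coef = iv.coef
    deg = len(coef) - 1
    lo, hi = iv.start, iv.stop
    if deg == 0:
        return None
    if deg == 1:
        return (lo, hi) if coef[1] < 0 else None
    # quadratic: split at the vertex, keep the decreasing side
    c1, c2 = coef[1], coef[2]
    if c2 == 0:
        return (lo, hi) if c1 < 0 else None
    z_vertex = iv.center - c1 / (2.0 * c2)
    zi = z[lo:hi]
    if c2 > 0:   # opens upward: decreasing left of the vertex
        k = int(np.searchsorted(zi, z_vertex, side="right"))
        return (lo, lo + k) if k > 0 else None
    k = int(np.searchsorted(zi, z_vertex, side="left"))
    return (lo + k, hi) if k < hi - lo else None


def detect_regions(curve: ForceCurve, seg: SegmentationResult, Zc: float,
                   config: InstrumentConfig | None = None,
                   merge_jump_tol: Optional[float] = None):
    """Regions of interest: decreasing spans of the smoothed retraction curve.

    For each segmentation interval the maximal sub-span where the polynomial
    is strictly decreasing is kept (for degree 2 the interval is split at the
    vertex).  Contiguous decreasing spans are merged when the polynomial jump
    at their junction stays below ``merge_jump_tol`` (an upward jump larger
    than that is a rupture and always separates regions); the default
    tolerance is three times the noise SD of the curve.

    Regions are then discarded when they (a) overlap the skip zone
    ``[Zc, Zc + skip_nm]``, (b) hold fewer than ``min_region_pts`` samples, or
    (c) contain any non-negative force sample (the FJC model only makes sense
    for adhesive forces).  Returns ``(list of (start, stop) index ranges,
    n_sign_dropped)``.
    """
    config = config or InstrumentConfig()
    if merge_jump_tol is None:
        merge_jump_tol = 3.0 * math.sqrt(max(estimate_noise_variance(curve), 0.0))
    z, F = curve.z, curve.F

    spans = []
    for iv in seg.intervals:
        sp = _decreasing_span(iv, z)
        if sp is None or sp[1] - sp[0] <= 0:
            continue
        # significance filter: the fitted drop across the span must exceed
        # the noise tolerance, otherwise a flat noise interval whose fitted
        # slope happens to be slightly negative would masquerade as a pull
        drop = float(iv(z[sp[0]]) - iv(z[sp[1] - 1]))
        if drop <= merge_jump_tol:
            continue
        spans.append(sp)

    # merge contiguous decreasing spans separated by a small (non-rupture) jump
    smooth = evaluate_piecewise(seg, curve)
    merged: List[Tuple[int, int]] = []
    for sp in spans:
        if merged and sp[0] <= merged[-1][1]:
            jump = smooth[sp[0]] - smooth[sp[0] - 1] if sp[0] > 0 else 0.0
            if jump <= merge_jump_tol:
                merged[-1] = (merged[-1][0], sp[1])
                continue
        merged.append(sp)

    skip_hi = Zc + config.skip_nm
    regions, n_sign_dropped = [], 0
    for a, b in merged:
        if z[a] <= skip_hi:            # overlaps the excluded near-contact zone
            continue
        if b - a < config.min_region_pts:
            continue
        if np.any(F[a:b] >= 0.0):      # positive force in a pulling region
            n_sign_dropped += 1
            continue
        regions.append((a, b))
    return regions, n_sign_dropped


# ---------------------------------------------------------------------------
# FJC fit
# ---------------------------------------------------------------------------

def _fjc_profile(lk, x, Fmag, Zc_to_zb, kbt):
    """Closed-form Lc (projected to >= z_b - Zc) and cost for a given lk."""
    g = langevin_factor(Fmag * lk / kbt)
    denom = float(g @ g)
    if denom <= 0:
        return math.nan, math.inf
    Lc = float(x @ g) / denom
    Lc = max(Lc, Zc_to_zb)
    resid = x - Lc * g
    return Lc, float(resid @ resid)


def fit_fjc_region(z, F, Zc: float, z_b: Optional[float] = None,
                   T: float = 298.15,
                   lk_bounds: Tuple[float, float] = DEFAULT_LK_BOUNDS,
                   lk_init: float = DEFAULT_LK_INIT) -> FJCRegionFit:
    """Fit one decreasing region to the FJC model.

    Minimises ``sum((z_i - Zc) - Lc g(|F_i|; lk))^2`` — the residual is in
    the extension coordinate, which makes the cost quadratic in ``Lc``: the
    inner solve is closed form with projection onto ``Lc >= z_b - Zc`` (the
    chain must at least reach the region's upper bound).  The outer 1-D
    problem over ``lk`` is scanned on a log grid including ``lk_init`` and
    refined by bounded Brent search.

    All forces must be negative (adhesive); raises :class:`FitError`
    otherwise or when the inner solve is degenerate.
    """
    z = np.asarray(z, dtype=float)
    F = np.asarray(F, dtype=float)
    if z.size < 3:
        raise FitError("FJC region needs at least 3 samples")
    if np.any(F >= 0):
        raise FitError("FJC fit requires strictly negative (adhesive) forces")
    lo, hi = lk_bounds
    if not 0 < lo < hi:
        raise FitError("lk bounds must satisfy 0 < lo < hi")
    if z_b is None:
        z_b = float(z[-1])
    x = z - Zc
    Fmag = np.abs(F)
    kbt = thermal_energy(T)
    Lmin = max(z_b - Zc, 0.0)

    grid = np.unique(np.append(np.geomspace(lo, hi, 60),
                               min(max(lk_init, lo), hi)))
    costs = np.array([_fjc_profile(lk, x, Fmag, Lmin, kbt)[1] for lk in grid])
    if not np.isfinite(costs).any():
        raise FitError("degenerate FJC region: Langevin factor vanishes")
    ib = int(np.argmin(costs))
    blo, bhi = grid[max(ib - 1, 0)], grid[min(ib + 1, grid.size - 1)]
    if blo < bhi:
        res = optimize.minimize_scalar(
            lambda lk: _fjc_profile(lk, x, Fmag, Lmin, kbt)[1],
            bounds=(blo, bhi), method="bounded", options={"xatol": 1e-8})
        lk = float(res.x) if res.fun <= costs[ib] else float(grid[ib])
    else:
        lk = float(grid[ib])
    Lc, sse = _fjc_profile(lk, x, Fmag, Lmin, kbt)
    if not np.isfinite(Lc):
        raise FitError("degenerate FJC region: Langevin factor vanishes")
    return FJCRegionFit(z_a=float(z[0]), z_b=float(z[-1]), Lc=Lc, lk=lk,
                        F_rupture=float(Fmag[-1]), sse=sse, n_pts=int(z.size))


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

def estimate_contact_point(curve: ForceCurve, seg: SegmentationResult,
                           tau: Optional[float] = None) -> float:
    """Contact point for retraction-only data.

    The smoothed force is followed outward from the minimum-z (contact) end:
    the contact point is where the initial repulsive part first drops below
    the threshold ``tau`` (3x the noise SD by default) — i.e. the smoothed
    zero crossing, made robust against the noise-flat region that follows.
    If the curve starts below threshold the first sample is returned.
    """
    if tau is None:
        tau = 3.0 * math.sqrt(max(estimate_noise_variance(curve), 0.0))
    smooth = evaluate_piecewise(seg, curve)
    if smooth[0] < tau:
        return float(curve.z[0])
    below = np.nonzero(smooth < tau)[0]
    if below.size == 0:
        return float(curve.z[-1])
    return float(curve.z[max(below[0] - 1, 0)])


def process_retract(curve: ForceCurve, Zc: Optional[float] = None,
                    config: InstrumentConfig | None = None, r: int = 1,
                    k_max: int = 20, eps: Optional[float] = None,
                    lk_bounds: Tuple[float, float] = DEFAULT_LK_BOUNDS,
                    lk_init: float = DEFAULT_LK_INIT) -> RetractFitResult:
    """Full retraction pipeline: preprocess, segment, detect regions, fit FJC.

    Segmentation defaults to piecewise affine (r=1) with at most 20
    discontinuities and the empirical noise variance as MSE threshold.  The
    contact point ``Zc`` normally comes from the paired approach fit (its Z1);
    when absent it is estimated from the smoothed zero crossing.
    """
    config = config or InstrumentConfig()
    pre = preprocess_curve(curve, config)
    noise_var = estimate_noise_variance(pre)
    if eps is None:
        eps = noise_var
    seg = segment_curve(pre, r=r, k_max=k_max, eps=eps)
    if Zc is None:
        Zc = estimate_contact_point(pre, seg)
    regions_idx, n_sign_dropped = detect_regions(pre, seg, Zc, config)
    fits: List[FJCRegionFit] = []
    for a, b in regions_idx:
        try:
            fits.append(fit_fjc_region(pre.z[a:b], pre.F[a:b], Zc,
                                       z_b=float(pre.z[b - 1]), T=config.T,
                                       lk_bounds=lk_bounds, lk_init=lk_init))
        except FitError:
            continue  # flagged unfit; region contributes nothing
    if fits:
        status = "ok"
    elif n_sign_dropped > 0:
        status = "excluded"   # decreasing regions existed but failed the sign test
    else:
        status = "no_regions"
    return RetractFitResult(status=status, Zc=float(Zc), regions=fits)
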