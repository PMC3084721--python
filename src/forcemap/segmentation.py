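"""Greedy change-point segmentation with piecewise polynomial smoothing.

A force curve is partitioned at discontinuity points (jumps, slope or
curvature changes) into contiguous intervals, each approximated by a
low-degree polynomial in the least-squares sense.  The search is greedy, in
the spirit of Orthogonal Least Squares: starting from a single interval, the
breakpoint whose insertion most reduces the total squared error is added at
each iteration, until a maximum count is reached or the global mean squared
error falls below a threshold (typically the empirical noise variance).

Intervals are half-open index ranges ``[a, b)`` (the last one closes the
curve); candidate breakpoints are data indices, and every interval must keep
at least ``r + 2`` samples so that squared-error comparisons between fits of
degree ``r`` remain meaningful.  Ties between equally good candidates are
broken towards the smallest index, so runs are deterministic.

The candidate scan uses cumulative power sums local to each interval
(accumulated from the interval's own end points, then centred and rescaled
before solving the normal equations), which makes one full scan O(n r^2)
without the catastrophic cancellation a global prefix-moment table would
suffer.  Stored interval fits are always direct least-squares refits.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb
from typing import List, Optional

import numpy as np

from .curves_io import ForceCurve
from .errors import FitError

__all__ = [
    "Interval",
    "SegmentationResult",
    "fit_poly_interval",
    "segment_curve",
    "evaluate_piecewise",
    "exhaustive_segment_oracle",
]

_TINY = 1e-300

#: SSE below this fraction of the signal energy is rounding noise from an
#: exact fit and is reported as exactly zero (so eps=0 stopping is reachable
#: on noise-free piecewise-polynomial signals).
_SSE_REL_FLOOR = 1e-14


def _floor_sse(sse, energy):
    return np.where(sse <= energy * _SSE_REL_FLOOR, 0.0, sse)


# ---------------------------------------------------------------------------
# single-interval fits
# ---------------------------------------------------------------------------

def _refit(z: np.ndarray, F: np.ndarray, r: int):
    """Direct LS fit of degree r.  Returns (coef about midpoint, center, sse)."""
    c = 0.5 * (z[0] + z[-1])
    t = z - c
    s = max(np.abs(t).max(), _TINY)
    V = np.vander(t / s, r + 1, increasing=True)
    beta, *_ = np.linalg.lstsq(V, F, rcond=None)
    resid = F - V @ beta
    coef = beta / s ** np.arange(r + 1)
    sse = float(_floor_sse(resid @ resid, F @ F))
    return coef, c, sse


def fit_poly_interval(z, F, r: int):
    """Ordinary least-squares polynomial fit on one interval.

    The polynomial is expressed in powers of ``z - c`` with ``c`` the interval
    midpoint ``(z[0] + z[-1]) / 2`` (for conditioning).  Returns
    ``(coefficients, SSE)`` with coefficients in ascending order.

    Raises :class:`FitError` for a degenerate design (all z equal with
    ``r >= 1``) or too few points.
    """
    z = np.asarray(z, dtype=float)
    F = np.asarray(F, dtype=float)
    if r not in (0, 1, 2, 3):
        raise FitError(f"polynomial degree must be in 0..3, got {r}")
    if z.size < r + 1:
        raise FitError(f"interval of {z.size} points cannot support degree {r}")
    if r >= 1 and np.ptp(z) == 0.0:
        raise FitError("degenerate design: all z values equal")
    coef, _c, sse = _refit(z, F, r)
    return coef, sse


# ---------------------------------------------------------------------------
# vectorised prefix scan
# ---------------------------------------------------------------------------

def _prefix_sse(z: np.ndarray, F: np.ndarray, r: int) -> np.ndarray:
    """SSE of the degree-r LS fit on every prefix ``[0, i)``.

    Returns ``out`` of length ``len(z) + 1`` with ``out[i]`` the prefix SSE,
    defined for ``i >= r + 2`` (``inf`` below that).  Power sums are taken
    about ``z[0]`` and re-centred/rescaled per prefix before solving the
    normal equations.
    """
    L = z.size
    out = np.full(L + 1, np.inf)
    if L < r + 2:
        return out
    zl = z - z[0]
    # cumulative raw moments about the interval start
    P = np.zeros((2 * r + 1, L + 1))
    Q = np.zeros((r + 1, L + 1))
    zp = np.ones_like(zl)
    for p in range(2 * r + 1):
        np.cumsum(zp, out=P[p, 1:])
        if p <= r:
            np.cumsum(zp * F, out=Q[p, 1:])
        zp = zp * zl
    SFF = np.concatenate(([0.0], np.cumsum(F * F)))

    idx = np.arange(r + 2, L + 1)
    half = zl[idx - 1] / 2.0          # midpoint of the prefix (also its scale)
    s = np.maximum(half, _TINY)
    ncand = idx.size
    T = np.empty((2 * r + 1, ncand))
    U = np.empty((r + 1, ncand))
    for p in range(2 * r + 1):
        acc = np.zeros(ncand)
        for q in range(p + 1):
            acc += comb(p, q) * (-half) ** (p - q) * P[q, idx]
        T[p] = acc / s ** p
        if p <= r:
            accq = np.zeros(ncand)
            for q in range(p + 1):
                accq += comb(p, q) * (-half) ** (p - q) * Q[q, idx]
            U[p] = accq / s ** p

    G = np.empty((ncand, r + 1, r + 1))
    for a in range(r + 1):
        for b in range(r + 1):
            G[:, a, b] = T[a + b]
    rhs = np.ascontiguousarray(U.T)
    try:
        coef = np.linalg.solve(G, rhs[..., None])[..., 0]
        fitted = np.einsum("ij,ij->i", coef, rhs)
    except np.linalg.LinAlgError:  # pragma: no cover - strictly increasing z
        fitted = np.empty(ncand)
        for i in range(ncand):
            sol, *_ = np.linalg.lstsq(G[i], rhs[i], rcond=None)
            fitted[i] = sol @ rhs[i]
    out[idx] = _floor_sse(np.maximum(SFF[idx] - fitted, 0.0), SFF[idx])
    return out


def _best_split(z: np.ndarray, F: np.ndarray, a: int, b: int, r: int):
    """Best single breakpoint inside interval [a, b).

    Returns ``(d, children_sse, parent_sse)`` or ``None`` if no admissible
    split exists.  ``d`` is the absolute data index of the breakpoint; ties
    are broken towards the smallest ``d``.
    """
    L = b - a
    m = r + 2
    if L < 2 * m:
        return None
    zi = z[a:b]
    Fi = F[a:b]
    left = _prefix_sse(zi, Fi, r)
    # right side: reverse and negate z so it is increasing again (SSE invariant)
    right_rev = _prefix_sse(-zi[::-1], Fi[::-1], r)
    lengths = np.arange(m, L - m + 1)
    totals = left[lengths] + right_rev[L - lengths]
    i = int(np.argmin(totals))  # argmin returns the first (smallest d) minimum
    return a + int(lengths[i]), float(totals[i]), float(left[L])


# ---------------------------------------------------------------------------
# results
# ---------------------------------------------------------------------------

@dataclass
class Interval:
    """One segmentation interval ``[start, stop)`` with its polynomial smoother."""

    start: int
    stop: int
    center: float
    coef: np.ndarray
    sse: float

    def __call__(self, z):
        return np.polynomial.polynomial.polyval(np.asarray(z) - self.center, self.coef)

    def derivative(self, z):
        der = np.polynomial.polynomial.polyder(self.coef)
        return np.polynomial.polynomial.polyval(np.asarray(z) - self.center, der)


@dataclass
class SegmentationResult:
    """Breakpoints, per-interval smoothers and the error trajectory."""

    breakpoints: List[int]
    intervals: List[Interval]
    mse_history: List[float]
    r: int
    stop_reason: str = "kmax"
    n: int = 0

    @property
    def total_sse(self) -> float:
        return float(sum(iv.sse for iv in self.intervals))

    def to_dict(self) -> dict:
        return {
            "breakpoints": [int(b) for b in self.breakpoints],
            "intervals": [
                {"start": iv.start, "stop": iv.stop, "center": iv.center,
                 "coef": list(map(float, iv.coef)), "sse": iv.sse}
                for iv in self.intervals
            ],
            "mse_history": list(map(float, self.mse_history)),
            "r": self.r,
            "stop_reason": self.stop_reason,
            "n": self.n,
        }


# ---------------------------------------------------------------------------
# greedy segmentation
# ---------------------------------------------------------------------------

def segment_curve(curve: ForceCurve, r: int = 2, k_max: int = 20,
                  eps: float = 0.0) -> SegmentationResult:
    """Greedy detection of up to ``k_max`` discontinuity points.

    Starting from a single global fit, the candidate breakpoint that
    minimises the total SSE over all intervals is inserted at each iteration
    (only the split interval is refitted).  Iteration stops when ``k_max``
    breakpoints are placed or when the global mean squared error
    ``total SSE / n`` drops to ``eps``, whichever happens first.

    An infeasible ``k_max`` is silently capped at the maximum the minimum
    interval length (``r + 2`` samples) permits; a curve shorter than
    ``2 (r + 2)`` samples comes back with zero breakpoints.
    """
    if k_max < 0:
        raise FitError("k_max must be >= 0")
    if eps < 0:
        raise FitError("eps must be >= 0")
    z, F, n = curve.z, curve.F, curve.n

    def direct(a, b):
        coef, c, sse = _refit(z[a:b], F[a:b], r)
        return Interval(a, b, c, coef, sse)

    intervals = {(0, n): direct(0, n)}
    split_cache = {(0, n): _best_split(z, F, 0, n, r)}
    breakpoints: List[int] = []
    total = intervals[(0, n)].sse
    mse_history = [total / n]
    stop_reason = "kmax"
    if mse_history[-1] <= eps:
        stop_reason = "mse_threshold"
    else:
        while len(breakpoints) < k_max:
            best_key, best_gain, best_split = None, 0.0, None
            # iterate in index order so ties resolve to the smallest breakpoint
            for key in sorted(intervals):
                cand = split_cache[key]
                if cand is None:
                    continue
                d, child_sse, _parent_scan = cand
                gain = intervals[key].sse - child_sse
                if best_key is None or gain > best_gain:
                    best_key, best_gain, best_split = key, gain, d
            if best_key is None:
                break  # k_max capped at the feasible maximum
            a, b = best_key
            d = best_split
            del intervals[best_key], split_cache[best_key]
            for sub in ((a, d), (d, b)):
                intervals[sub] = direct(*sub)
                split_cache[sub] = _best_split(z, F, sub[0], sub[1], r)
            breakpoints.append(d)
            total = sum(iv.sse for iv in intervals.values())
            mse_history.append(total / n)
            if mse_history[-1] <= eps:
                stop_reason = "mse_threshold"
                break
    ordered = [intervals[k] for k in sorted(intervals)]
    return SegmentationResult(
        breakpoints=sorted(breakpoints), intervals=ordered,
        mse_history=mse_history, r=r, stop_reason=stop_reason, n=n)


def evaluate_piecewise(seg: SegmentationResult, curve: ForceCurve) -> np.ndarray:
    """Smoothed force: each interval's polynomial evaluated at its own samples."""
    out = np.empty(curve.n)
    for iv in seg.intervals:
        out[iv.start:iv.stop] = iv(curve.z[iv.start:iv.stop])
    return out


# ---------------------------------------------------------------------------
# exhaustive oracle (test-scale only)
# ---------------------------------------------------------------------------

def exhaustive_segment_oracle(curve: ForceCurve, r: int, k: int) -> List[int]:
    """Globally SSE-optimal ``k`` breakpoints by exhaustive enumeration.

    Tractable only at test scale; refuses ``n > 300`` or ``k > 2``.  Ties are
    broken towards the lexicographically smallest breakpoint tuple.
    """
    n = curve.n
    if n > 300 or k > 2:
        raise FitError("exhaustive oracle limited to n <= 300 and k <= 2")
    if k == 0:
        return []
    z, F = curve.z, curve.F
    m = r + 2
    cache: dict = {}

    def S(a, b):
        key = (a, b)
        if key not in cache:
            cache[key] = fit_poly_interval(z[a:b], F[a:b], r)[1]
        return cache[key]

    best: Optional[tuple] = None
    best_sse = np.inf
    if k == 1:
        for d in range(m, n - m + 1):
            t = S(0, d) + S(d, n)
            if t < best_sse:
                best, best_sse = (d,), t
    else:
        for d1 in range(m, n - 2 * m + 1):
            s0 = S(0, d1)
            for d2 in range(d1 + m, n - m + 1):
                t = s0 + S(d1, d2) + S(d2, n)
                if t < best_sse:
                    best, best_sse = (d1, d2), t
    if best is None:
        raise FitError(f"no admissible {k}-breakpoint segmentation for n={n}, r={r}")
    return list(best)
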