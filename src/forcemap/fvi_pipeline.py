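"""Whole-image processing: per-pixel fits, parameter maps, histograms, tables.

Force curves are processed sequentially and independently with one shared
configuration, so results are deterministic and a sub-grid processes to
exactly the same values as the full grid.  Failed pixels are masked (NaN) in
the maps; retraction pixels with no detected region contribute zero adhesion
(polymers absent or not detectable there).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .approach_fit import ApproachFitResult, process_approach
from .curves_io import FVImage, write_matrix_tsv
from .errors import DataError
from .retract_fit import RetractFitResult, process_retract

__all__ = [
    "ParameterMap",
    "FVIResultBundle",
    "make_histogram",
    "process_fvi_approach",
    "process_fvi_retract",
    "write_bundle",
]


@dataclass
class ParameterMap:
    """A fitted scalar on the FVI grid with a validity mask."""

    name: str
    values: np.ndarray          # H x W floats; NaN where masked
    mask: np.ndarray            # H x W bool; True = valid
    units: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.shape != self.mask.shape or self.values.ndim != 2:
            raise DataError("map values and mask must be 2-D and same shape")
        self.values = np.where(self.mask, self.values, np.nan)

    @property
    def valid_values(self) -> np.ndarray:
        return self.values[self.mask]


@dataclass
class FVIResultBundle:
    maps: Dict[str, ParameterMap] = field(default_factory=dict)
    histograms: Dict[str, Tuple[np.ndarray, np.ndarray]] = field(default_factory=dict)
    per_pixel: Optional[pd.DataFrame] = None


def make_histogram(values, bins="fd") -> Tuple[np.ndarray, np.ndarray]:
    """(edges, counts) histogram; Freedman-Diaconis bins by default.

    Degenerate inputs (empty, constant) fall back to a single bin; counts
    always sum to the number of finite input values.
    """
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size == 0:
        return np.array([0.0, 1.0]), np.array([0])
    if v.size < 2 or np.ptp(v) <= 1e-12 * max(np.abs(v).max(), 1.0):
        # effectively constant data: one bin around the common value
        half = max(abs(v[0]) * 0.5, 0.5)
        return np.array([v.min() - half, v.max() + half]), np.array([v.size])
    try:
        counts, edges = np.histogram(v, bins=bins)
    except (ValueError, MemoryError):
        counts, edges = np.histogram(v, bins=10)
    if counts.size > 512:  # FD can explode on heavy-tailed data
        counts, edges = np.histogram(v, bins=512)
    return edges, counts


def _new_map(name, H, W, units=""):
    return ParameterMap(name, np.full((H, W), np.nan), np.zeros((H, W), bool), units)


def _set(pmap: ParameterMap, r, c, value):
    if value is not None and np.isfinite(value):
        pmap.values[r, c] = value
        pmap.mask[r, c] = True


def process_fvi_approach(fvi: FVImage, bins="fd", **kwargs) -> FVIResultBundle:
    """Run :func:`process_approach` on every approach pixel of the image.

    Produces maps of topography (``max(Z1) - Z1`` over valid pixels), the
    electrostatic prefactor A, the Debye length kappa^-1, the Young modulus E
    and the cell spring constant k_cell, plus per-parameter histograms and a
    per-pixel table.  Extra keyword arguments go to ``process_approach``.
    """
    H, W = fvi.height, fvi.width
    maps = {
        "Z1": _new_map("Z1", H, W, "nm"),
        "A": _new_map("A", H, W, "nN"),
        "kappa_inv": _new_map("kappa_inv", H, W, "nm"),
        "E": _new_map("E", H, W, "Pa"),
        "k_cell": _new_map("k_cell", H, W, "N/m"),
    }
    rows = []
    for r in range(H):
        for c in range(W):
            curve = fvi.approach[r][c] if fvi.approach else None
            if curve is None:
                rows.append({"row": r, "col": c, "status": "missing"})
                continue
            res: ApproachFitResult = process_approach(curve, fvi.config, **kwargs)
            _set(maps["Z1"], r, c, res.Z1)
            _set(maps["A"], r, c, res.A)
            _set(maps["kappa_inv"], r, c, res.kappa_inv)
            _set(maps["E"], r, c, res.E)
            _set(maps["k_cell"], r, c, res.k_cell)
            row = {"row": r, "col": c}
            row.update(res.to_dict())
            rows.append(row)
    z1 = maps["Z1"]
    topo_vals = np.nanmax(z1.values) - z1.values if z1.mask.any() else z1.values
    maps["topography"] = ParameterMap("topography", topo_vals, z1.mask.copy(), "nm")
    histograms = {name: make_histogram(m.valid_values, bins=bins)
                  for name, m in maps.items()}
    per_pixel = pd.DataFrame(rows)
    return FVIResultBundle(maps=maps, histograms=histograms, per_pixel=per_pixel)


def process_fvi_retract(fvi: FVImage, bins="fd", use_approach_zc: bool = True,
                        **kwargs) -> FVIResultBundle:
    """Run :func:`process_retract` on every retraction pixel of the image.

    The contact point per pixel is taken from the paired approach fit (Z1)
    when an approach curve is present and ``use_approach_zc`` is set,
    otherwise estimated from the retraction curve itself.  Produces maps of
    the last adhesion force and last rupture distance (zero where no region
    was detected), and pooled histograms of Lc, lk, N, deltaL, the last
    adhesion force and the rupture count.
    """
    H, W = fvi.height, fvi.width
    f_map = _new_map("last_adhesion_force", H, W, "nN")
    d_map = _new_map("last_rupture_distance", H, W, "nm")
    pooled: Dict[str, List[float]] = {k: [] for k in
                                      ("Lc", "lk", "N", "deltaL",
                                       "last_adhesion_force", "n_ruptures")}
    rows = []
    for r in range(H):
        for c in range(W):
            curve = fvi.retract[r][c] if fvi.retract else None
            if curve is None:
                rows.append({"row": r, "col": c, "status": "missing"})
                continue
            Zc = None
            if use_approach_zc and fvi.approach and fvi.approach[r][c] is not None:
                ares = process_approach(fvi.approach[r][c], fvi.config)
                if np.isfinite(ares.Z1):
                    Zc = ares.Z1
            res: RetractFitResult = process_retract(curve, Zc=Zc,
                                                    config=fvi.config, **kwargs)
            # pixels with nothing detected contribute zero adhesion
            _set(f_map, r, c, res.last_adhesion_force)
            _set(d_map, r, c, res.last_rupture_distance)
            for reg in res.regions:
                pooled["Lc"].append(reg.Lc)
                pooled["lk"].append(reg.lk)
                pooled["N"].append(reg.N)
                pooled["last_adhesion_force"].append(res.last_adhesion_force)
            pooled["deltaL"].extend(res.deltaL)
            if res.regions:
                pooled["n_ruptures"].append(res.n_ruptures)
            rows.append({"row": r, "col": c, "status": res.status,
                         "Zc": res.Zc, "n_regions": len(res.regions),
                         "n_ruptures": res.n_ruptures,
                         "last_adhesion_force": res.last_adhesion_force,
                         "last_rupture_distance": res.last_rupture_distance})
    # histogram of the last adhesion force should be per pixel, not per region
    pooled["last_adhesion_force"] = list(f_map.valid_values)
    histograms = {k: make_histogram(vals) for k, vals in pooled.items()}
    maps = {"last_adhesion_force": f_map, "last_rupture_distance": d_map}
    return FVIResultBundle(maps=maps, histograms=histograms,
                           per_pixel=pd.DataFrame(rows))


def write_bundle(bundle: FVIResultBundle, outdir, metadata: Optional[dict] = None
                 ) -> Path:
    """Write maps, histograms, the per-pixel table and run metadata to a dir.

    Maps go to ``<name>.tsv`` matrices (NaN = masked), histograms to
    ``hist_<name>.tsv`` (bin_lo, bin_hi, count), the table to
    ``per_pixel.tsv`` and metadata to ``metadata.json``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name, pmap in bundle.maps.items():
        write_matrix_tsv(pmap, outdir / f"{name}.tsv")
    for name, (edges, counts) in bundle.histograms.items():
        with open(outdir / f"hist_{name}.tsv", "w") as fh:
            fh.write("bin_lo\tbin_hi\tcount\n")
            for lo, hi, ct in zip(edges[:-1], edges[1:], counts):
                fh.write(f"{lo:.17g}\t{hi:.17g}\t{int(ct)}\n")
    if bundle.per_pixel is not None:
        bundle.per_pixel.to_csv(outdir / "per_pixel.tsv", sep="\t", index=False)
    if metadata is not None:
        (outdir / "metadata.json").write_text(json.dumps(metadata, indent=1,
                                                         default=str))
    return outdir
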