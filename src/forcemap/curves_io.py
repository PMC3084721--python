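"""Reading, writing and pre-processing of AFM force curves and force-volume
images (FVIs).

A force curve is a pair of equal-length arrays: piezo position ``z`` (nm) and
force ``F`` (nN).  The orientation convention is that ``z`` increases towards
probe-sample contact for approach curves (contact at the largest ``z``) and
away from contact for retraction curves (contact at the smallest ``z``).
Raw instrument output may record cantilever deflection instead of force; the
conversion is Hooke's law, ``F = k_c * d``.

Pre-processing brings a raw curve into the canonical form every fitting stage
assumes: ``z`` strictly increasing (duplicates averaged), and an affine
baseline, estimated on the far-from-contact end, subtracted from ``F``.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np

from .errors import ConfigError, DataError, ParseError

__all__ = [
    "ForceCurve",
    "InstrumentConfig",
    "FVImage",
    "parse_curve_file",
    "write_curve_file",
    "preprocess_curve",
    "estimate_noise_variance",
    "read_fvi",
    "write_fvi",
    "write_matrix_tsv",
    "read_matrix_tsv",
]

MIN_CURVE_POINTS = 10


@dataclass
class ForceCurve:
    """One approach or retraction force record.

    Attributes
    ----------
    z : ndarray
        Piezo positions, nm.
    F : ndarray
        Forces, nN.
    direction : str
        ``"approach"`` or ``"retract"``.
    k_c : float
        Cantilever spring constant, nN/nm.
    pixel : tuple of int, optional
        (row, col) grid coordinate inside an FVI.
    """

    z: np.ndarray
    F: np.ndarray
    direction: str = "approach"
    k_c: float = 0.0104
    pixel: Optional[tuple] = None

    def __post_init__(self):
        self.z = np.asarray(self.z, dtype=float)
        self.F = np.asarray(self.F, dtype=float)
        if self.z.ndim != 1 or self.F.ndim != 1 or self.z.size != self.F.size:
            raise DataError("z and F must be 1-D arrays of equal length")
        if self.z.size < MIN_CURVE_POINTS:
            raise DataError(
                f"force curve needs at least {MIN_CURVE_POINTS} samples, got {self.z.size}"
            )
        if not (np.isfinite(self.z).all() and np.isfinite(self.F).all()):
            raise DataError("force curve contains non-finite values")
        if self.direction not in ("approach", "retract"):
            raise DataError(f"unknown direction {self.direction!r}")
        if self.k_c <= 0:
            raise DataError("cantilever spring constant must be positive")

    @property
    def n(self) -> int:
        return self.z.size


@dataclass
class InstrumentConfig:
    """Instrument constants and pre-processing/analysis settings.

    Parameters
    ----------
    k_c : float
        Cantilever spring constant, nN/nm (thermal calibration gives
        ~10.4 pN/nm for the soft levers used on bacteria).
    alpha : float
        Tip semi-top angle in degrees (conical tip).
    nu : float
        Poisson coefficient of the sample; 0.5 for an incompressible medium.
    T : float
        Temperature, K.
    c_inf : float
        Bulk concentration of the 1:1 electrolyte, mol/L.
    eps_r : float
        Relative permittivity of the medium.
    A_max : float or None
        Upper bound on the electrostatic prefactor (force at the contact
        point), nN.  ``None`` selects an automatic bound of twice the largest
        force inside the electrostatic window.
    baseline_n : int
        Number of far-from-contact samples used for the affine baseline.
    skip_nm : float
        Initial retraction span (past the contact point) excluded from FJC
        analysis.
    min_region_pts : int
        Minimum number of samples for a retraction region of interest.
    """

    k_c: float = 0.0104
    alpha: float = 35.0
    nu: float = 0.5
    T: float = 298.15
    c_inf: float = 1e-3
    eps_r: float = 78.5
    A_max: Optional[float] = None
    baseline_n: int = 500
    skip_nm: float = 100.0
    min_region_pts: int = 5

    def __post_init__(self):
        if min(self.k_c, self.T, self.c_inf, self.eps_r) <= 0:
            raise ConfigError("physical quantities in InstrumentConfig must be > 0")
        if not 0 <= self.nu <= 0.5 + 1e-9:
            raise ConfigError("Poisson coefficient must lie in [0, 0.5]")
        if not 0 < self.alpha < 90:
            raise ConfigError("tip semi-top angle must lie in (0, 90) degrees")
        if self.baseline_n < 4 or self.min_region_pts < 2:
            raise ConfigError("window sizes too small")
        if self.skip_nm < 0:
            raise ConfigError("skip_nm must be non-negative")
        if self.A_max is not None and self.A_max <= 0:
            raise ConfigError("A_max must be positive when given")

    @classmethod
    def from_dict(cls, d: dict) -> "InstrumentConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)


@dataclass
class FVImage:
    """A force-volume image: a grid of force-curve pairs plus instrument config.

    ``approach[row][col]`` / ``retract[row][col]`` hold :class:`ForceCurve`
    objects or ``None`` for masked pixels.
    """

    width: int
    height: int
    pixel_size: float
    approach: list = field(default_factory=list)
    retract: list = field(default_factory=list)
    config: InstrumentConfig = field(default_factory=InstrumentConfig)

    def __post_init__(self):
        if self.width <= 0 or self.height <= 0:
            raise ConfigError("FVI grid dimensions must be positive")
        for grid in (self.approach, self.retract):
            if grid and (len(grid) != self.height or any(len(r) != self.width for r in grid)):
                raise ConfigError("curve grid shape does not match width/height")

    @staticmethod
    def empty_grid(height: int, width: int) -> list:
        return [[None] * width for _ in range(height)]


# ---------------------------------------------------------------------------
# curve files
# ---------------------------------------------------------------------------

def parse_curve_file(path, dialect: str = "z_force", *, k_c: float = 0.0104,
                     direction: str = "approach", pixel=None) -> ForceCurve:
    """Read a two-column numeric text file into a raw :class:`ForceCurve`.

    Columns are separated by commas and/or whitespace; lines starting with
    ``#`` (and blank lines) are ignored.  Column 1 is always the piezo
    position z in nm.  ``dialect`` declares column 2: ``"z_force"`` means
    force in nN, ``"z_deflection"`` means cantilever deflection in nm, which
    is converted to force as ``F = k_c * d``.

    No reordering or baseline subtraction is performed here; see
    :func:`preprocess_curve`.
    """
    if dialect not in ("z_force", "z_deflection"):
        raise ConfigError(f"unknown dialect {dialect!r}")
    zs, ys = [], []
    with open(path, "r") as fh:
        for lineno, line in enumerate(fh, start=1):
            s = line.strip()
            if not s or s.startswith("#"):
                continue
            parts = s.replace(",", " ").split()
            if len(parts) != 2:
                raise ParseError(f"{path}: line {lineno}: expected 2 columns, got {len(parts)}")
            try:
                zv, yv = float(parts[0]), float(parts[1])
            except ValueError:
                raise ParseError(f"{path}: line {lineno}: non-numeric value") from None
            if not (np.isfinite(zv) and np.isfinite(yv)):
                raise DataError(f"{path}: line {lineno}: non-finite value")
            zs.append(zv)
            ys.append(yv)
    if len(zs) < MIN_CURVE_POINTS:
        raise DataError(f"{path}: fewer than {MIN_CURVE_POINTS} data rows")
    z = np.array(zs)
    y = np.array(ys)
    F = k_c * y if dialect == "z_deflection" else y
    return ForceCurve(z=z, F=F, direction=direction, k_c=k_c, pixel=pixel)


def write_curve_file(curve: ForceCurve, path, header: str = "") -> None:
    """Write a curve as two-column text (z_force dialect), 17 significant digits."""
    with open(path, "w") as fh:
        if header:
            for line in header.splitlines():
                fh.write(f"# {line}\n")
        for zv, fv in zip(curve.z, curve.F):
            fh.write(f"{zv:.17g} {fv:.17g}\n")


# ---------------------------------------------------------------------------
# pre-processing
# ---------------------------------------------------------------------------

def _noncontact_slice(n: int, m: int, direction: str) -> slice:
    """Index window of m samples at the far-from-contact end of a sorted curve."""
    if direction == "approach":
        return slice(0, m)  # contact at largest z
    return slice(n - m, n)  # retract: contact at smallest z


def preprocess_curve(curve: ForceCurve, config: InstrumentConfig | None = None) -> ForceCurve:
    """Sort by z, average duplicate z samples and subtract an affine baseline.

    The baseline is an ordinary least-squares affine fit of F against z over
    the ``baseline_n`` samples at the far-from-contact end (the first sorted
    samples for an approach curve, the last for a retraction curve).  If the
    curve is shorter than ``baseline_n`` the window shrinks to n/4 with a
    warning.  The input curve is not modified.
    """
    config = config or InstrumentConfig()
    order = np.argsort(curve.z, kind="stable")
    z = curve.z[order]
    F = curve.F[order]
    # average exact-duplicate z values so z is strictly increasing
    zu, inverse, counts = np.unique(z, return_inverse=True, return_counts=True)
    if zu.size != z.size:
        Fsum = np.zeros(zu.size)
        np.add.at(Fsum, inverse, F)
        F = Fsum / counts
        z = zu
    n = z.size
    if n < MIN_CURVE_POINTS:
        raise DataError("too few distinct z values after duplicate averaging")
    m = config.baseline_n
    if n <= m:
        m = max(n // 4, 2)
        warnings.warn(
            f"curve has {n} samples <= baseline_n={config.baseline_n}; "
            f"baseline window shrunk to {m}",
            stacklevel=2,
        )
    win = _noncontact_slice(n, m, curve.direction)
    coeffs = np.polynomial.polynomial.polyfit(z[win], F[win], 1)
    F = F - np.polynomial.polynomial.polyval(z, coeffs)
    return replace(curve, z=z, F=F)


def estimate_noise_variance(curve: ForceCurve, flat_fraction: float = 0.25) -> float:
    """Unbiased sample variance (nN^2) of F over the flat, non-contact end.

    The window is ``flat_fraction * n`` samples at the far-from-contact end of
    a pre-processed curve.  Used as the default mean-squared-error threshold
    for the segmentation stopping rule.
    """
    if not 0 < flat_fraction <= 1:
        raise ConfigError("flat_fraction must lie in (0, 1]")
    n = curve.n
    m = int(flat_fraction * n)
    if m < 10:
        raise DataError(f"noise window has {m} < 10 samples")
    win = _noncontact_slice(n, m, curve.direction)
    return float(np.var(curve.F[win], ddof=1))


# ---------------------------------------------------------------------------
# FVI manifest I/O
# ---------------------------------------------------------------------------

def read_fvi(manifest_path, preprocess: bool = True) -> FVImage:
    """Load a force-volume image described by a JSON manifest.

    Manifest schema::

        {"width": W, "height": H, "pixel_size_nm": s,
         "config": {...InstrumentConfig fields...},
         "pixels": [{"row": r, "col": c,
                     "approach": "relative/path.txt",   # optional
                     "retract": "relative/path.txt"},   # optional
                    ...]}

    Curve files live beside the manifest.  Missing pixel entries are allowed
    and come back masked (``None``).  Curves are pre-processed on load unless
    ``preprocess=False``.
    """
    manifest_path = Path(manifest_path)
    try:
        manifest = json.loads(manifest_path.read_text())
    except FileNotFoundError:
        raise ConfigError(f"manifest not found: {manifest_path}") from None
    except json.JSONDecodeError as exc:
        raise ConfigError(f"manifest is not valid JSON: {exc}") from None

    for key in ("width", "height", "pixel_size_nm", "pixels"):
        if key not in manifest:
            raise ConfigError(f"manifest missing required key {key!r}")
    width = int(manifest["width"])
    height = int(manifest["height"])
    pixels = manifest["pixels"]
    if not isinstance(pixels, list):
        raise ConfigError("manifest 'pixels' must be a list")
    if len(pixels) > width * height:
        raise ConfigError(
            f"manifest lists {len(pixels)} pixels for a {width}x{height} grid"
        )
    config = InstrumentConfig.from_dict(manifest.get("config", {}))

    approach = FVImage.empty_grid(height, width)
    retract = FVImage.empty_grid(height, width)
    seen = set()
    for entry in pixels:
        try:
            r, c = int(entry["row"]), int(entry["col"])
        except (KeyError, TypeError, ValueError):
            raise ConfigError(f"malformed pixel entry: {entry!r}") from None
        if not (0 <= r < height and 0 <= c < width):
            raise ConfigError(f"pixel ({r}, {c}) outside {width}x{height} grid")
        if (r, c) in seen:
            raise ConfigError(f"duplicate pixel entry ({r}, {c})")
        seen.add((r, c))
        for kind, grid, direction in (("approach", approach, "approach"),
                                      ("retract", retract, "retract")):
            rel = entry.get(kind)
            if rel is None:
                continue
            fpath = manifest_path.parent / rel
            if not fpath.exists():
                raise ConfigError(f"pixel ({r}, {c}): curve file missing: {fpath}")
            curve = parse_curve_file(fpath, "z_force", k_c=config.k_c,
                                     direction=direction, pixel=(r, c))
            grid[r][c] = preprocess_curve(curve, config) if preprocess else curve
    return FVImage(width=width, height=height,
                   pixel_size=float(manifest["pixel_size_nm"]),
                   approach=approach, retract=retract, config=config)


def write_fvi(fvi: FVImage, outdir, manifest_name: str = "manifest.json") -> Path:
    """Serialize an FVImage to a manifest plus one text file per curve.

    Returns the manifest path.  Pixels where both curves are ``None`` are
    omitted from the manifest (masked).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = {k: getattr(fvi.config, k) for k in InstrumentConfig.__dataclass_fields__}
    pixels = []
    for r in range(fvi.height):
        for c in range(fvi.width):
            entry = {"row": r, "col": c}
            for kind, grid in (("approach", fvi.approach), ("retract", fvi.retract)):
                curve = grid[r][c] if grid else None
                if curve is None:
                    continue
                rel = f"{kind}_{r:03d}_{c:03d}.txt"
                write_curve_file(curve, outdir / rel, header=f"pixel ({r}, {c}) {kind}")
                entry[kind] = rel
            if len(entry) > 2:
                pixels.append(entry)
    manifest = {"width": fvi.width, "height": fvi.height,
                "pixel_size_nm": fvi.pixel_size, "config": cfg, "pixels": pixels}
    path = outdir / manifest_name
    path.write_text(json.dumps(manifest, indent=1))
    return path


# ---------------------------------------------------------------------------
# matrix TSV
# ---------------------------------------------------------------------------

def write_matrix_tsv(values, path, mask=None) -> None:
    """Write a 2-D float array as TSV, one line per row, ``NaN`` for masked cells.

    ``values`` may be an ndarray or any object with ``values``/``mask``
    attributes (a ParameterMap).  17 significant digits so a read-back
    reproduces the array bit-exactly.
    """
    if hasattr(values, "values") and hasattr(values, "mask"):
        mask = values.mask
        values = values.values
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 2:
        raise DataError("write_matrix_tsv expects a 2-D array")
    if mask is not None:
        arr = np.where(np.asarray(mask, dtype=bool), arr, np.nan)
    try:
        with open(path, "w") as fh:
            for row in arr:
                fh.write("\t".join("NaN" if np.isnan(v) else f"{v:.17g}" for v in row))
                fh.write("\n")
    except OSError as exc:
        raise DataError(f"cannot write {path}: {exc}") from None


def read_matrix_tsv(path) -> np.ndarray:
    """Read a TSV matrix written by :func:`write_matrix_tsv` (NaN = masked)."""
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.strip():
                rows.append([float(tok) for tok in line.split("\t")])
    return np.array(rows, dtype=float)
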