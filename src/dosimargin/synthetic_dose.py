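"""Phantom geometry and parametric 3-D dose fields for SBRT margin studies.

This module emulates the dose distributions of two lung-SBRT planning styles
on a spherical water-equivalent tumor embedded in lung:

* **point (isocenter) prescription** — the prescribed dose is delivered at the
  isocenter and falls off gently through the target, as is typical of 3D-CRT
  beam arrangements;
* **marginal prescription** — the dose is normalised so that the PTV D95%
  equals the prescription and the prescription isodose surface sits at a
  chosen level (60–80%) of the maximum dose, as is typical of VMAT SBRT.

All fields are radially symmetric about the tumor center and monotonically
non-increasing with distance, built from a smooth sigmoidal shoulder
``D(ρ) = D_max · Φ((R50 − ρ)/w)`` (Φ the standard normal CDF) with, for the
point style, an additional linear core gradient.  The penumbra width ``w``
is the single knob standing in for lateral electron transport: lower lung /
tumor electron density broadens the shoulder (see :func:`density_to_penumbra`).

For the marginal style the effective shoulder width additionally scales with
the prescription isodose level as ``w_eff = w · (80/ID)^3``: plans prescribed
to a lower isodose line (hotter core) are generated with a proportionally
wider shoulder.  This reproduces the empirical ordering that a 60%
prescription carries larger dosimetric margins than an 80% prescription —
equivalently, the relative falloff just outside the prescription surface is
steeper at higher ID.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, replace
from functools import lru_cache
from pathlib import Path
from typing import Literal, Mapping

import numpy as np
from scipy.optimize import brentq
from scipy.special import ndtr

__all__ = [
    "AXES",
    "GridSpec",
    "PhantomSpec",
    "SphereStructure",
    "DoseProfileParams",
    "DoseGrid",
    "NormalizationError",
    "make_phantom",
    "generate_dose",
    "density_to_penumbra",
    "coverage_radius",
    "write_dose_grid",
    "read_dose_grid",
    "write_structure_mask",
]

#: Cardinal patient axes, mapped to grid axes 0/1/2 (x, y, z).
AXES = ("LR", "AP", "CC")

#: Isodose level (percent of D_max) at which the marginal shoulder width
#: equals the nominal penumbra width.
REFERENCE_ISODOSE = 80.0

#: Exponent of the (80/ID) scaling of the marginal shoulder width.
ID_FALLOFF_EXPONENT = 3.0

#: Penumbra width anchors of the density mapping: (electron density g/cm^3, mm).
PENUMBRA_ANCHOR_HIGH = (1.0, 4.0)
PENUMBRA_ANCHOR_LOW = (0.4, 8.0)

#: Metadata key recording the stored quantity in grid files.
QUANTITY_KEY = "dosimargin.quantity"


class NormalizationError(ValueError):
    """Raised when a requested dose normalisation cannot be realised."""


# ---------------------------------------------------------------------------
# Grid and geometry
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GridSpec:
    """Regular 3-D grid: voxel counts, spacing (mm) and origin (mm).

    The origin is the coordinate of the *center* of voxel (0, 0, 0).
    """

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float]

    def __post_init__(self) -> None:
        object.__setattr__(self, "shape", tuple(int(n) for n in self.shape))
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))
        if len(self.shape) != 3 or len(self.spacing) != 3 or len(self.origin) != 3:
            raise ValueError("GridSpec requires 3-D shape, spacing and origin")
        if any(n < 1 for n in self.shape):
            raise ValueError("grid shape must be >= 1 on every axis")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("grid spacing must be positive on every axis")

    @classmethod
    def centered(cls, half_extent: float = 48.0, spacing: float = 2.0) -> "GridSpec":
        """Isotropic grid symmetric about the origin with a voxel center at 0.

        The default (±48 mm at 2 mm spacing) leaves room for the PTV, the full
        ±20 mm shift scan and the widest default penumbra.
        """
        n = 2 * int(round(half_extent / spacing)) + 1
        o = -spacing * (n // 2)
        return cls((n, n, n), (spacing, spacing, spacing), (o, o, o))

    def axis_coords(self, axis: int) -> np.ndarray:
        return self.origin[axis] + self.spacing[axis] * np.arange(self.shape[axis])

    def coords(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Sparse broadcastable voxel-center coordinate arrays."""
        x = self.axis_coords(0)[:, None, None]
        y = self.axis_coords(1)[None, :, None]
        z = self.axis_coords(2)[None, None, :]
        return x, y, z

    def bounds(self) -> tuple[tuple[float, float], ...]:
        """(min, max) voxel-center coordinate per axis."""
        return tuple(
            (self.origin[i], self.origin[i] + self.spacing[i] * (self.shape[i] - 1))
            for i in range(3)
        )

    def contains_sphere(self, center: tuple[float, float, float], radius: float) -> bool:
        return all(
            lo <= c - radius and c + radius <= hi
            for (lo, hi), c in zip(self.bounds(), center)
        )

    def radial_distance(self, center: tuple[float, float, float]) -> np.ndarray:
        x, y, z = self.coords()
        return np.sqrt(
            (x - center[0]) ** 2 + (y - center[1]) ** 2 + (z - center[2]) ** 2
        )


@dataclass(frozen=True)
class PhantomSpec:
    """Spherical lung-tumor phantom: GTV radius and CTV/PTV expansion margins.

    Densities are electron densities relative to water (g/cm^3); the tumor
    density feeds the penumbra mapping, the lung density is carried as
    metadata of the scenario.
    """

    gtv_radius: float = 10.0
    ctv_margin: float = 0.0
    ptv_margin: float = 5.0
    tumor_density: float = 1.0
    lung_density: float = 0.3

    def __post_init__(self) -> None:
        if self.gtv_radius <= 0:
            raise ValueError("gtv_radius must be > 0")
        if self.ctv_margin < 0:
            raise ValueError("ctv_margin must be >= 0")
        margin = np.atleast_1d(np.asarray(self.ptv_margin, dtype=float))
        if margin.size not in (1, 3):
            raise ValueError("ptv_margin must be a scalar or one value per axis")
        if np.ptp(margin) != 0:
            raise ValueError("anisotropic PTV margins are not supported (spheres only)")
        object.__setattr__(self, "ptv_margin", float(margin.flat[0]))
        if self.ptv_margin <= 0:
            raise ValueError("ptv_margin must be > 0")
        for name in ("tumor_density", "lung_density"):
            rho = getattr(self, name)
            if not 0 < rho <= 2:
                raise ValueError(f"{name} must lie in (0, 2] g/cm^3")

    @property
    def ctv_radius(self) -> float:
        return self.gtv_radius + self.ctv_margin

    @property
    def ptv_radius(self) -> float:
        return self.ctv_radius + self.ptv_margin


@dataclass(frozen=True)
class SphereStructure:
    """A spherical region of interest (GTV, CTV or PTV) on a grid.

    Rasterisation rule (fixed): a voxel belongs to the sphere iff its center
    lies inside or on the surface (``|x - c| <= r``).
    """

    center: tuple[float, float, float]
    radius: float
    label: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "center", tuple(float(c) for c in self.center))
        if self.radius <= 0:
            raise ValueError("structure radius must be > 0")

    def indices(self, grid: GridSpec) -> np.ndarray:
        """Flat indices of member voxels (cached per grid/center/radius)."""
        return _sphere_indices(grid, self.center, self.radius)

    def mask(self, grid: GridSpec) -> np.ndarray:
        m = np.zeros(grid.shape, dtype=bool)
        m.ravel()[self.indices(grid)] = True
        return m

    def translated(self, offset: tuple[float, float, float]) -> "SphereStructure":
        c = tuple(a + b for a, b in zip(self.center, offset))
        return replace(self, center=c)


@lru_cache(maxsize=16384)
def _sphere_indices(
    grid: GridSpec, center: tuple[float, float, float], radius: float
) -> np.ndarray:
    d2 = (
        (grid.axis_coords(0)[:, None, None] - center[0]) ** 2
        + (grid.axis_coords(1)[None, :, None] - center[1]) ** 2
        + (grid.axis_coords(2)[None, None, :] - center[2]) ** 2
    )
    idx = np.flatnonzero(d2.ravel() <= radius * radius)
    idx.setflags(write=False)
    return idx


@dataclass(frozen=True)
class DoseProfileParams:
    """Parameters of the radial dose profile.

    prescription_style
        ``"point"`` — normalised to the prescription dose at the center voxel;
        ``"marginal"`` — normalised so PTV D95% equals the prescription and the
        prescription surface sits at ``isodose_level`` % of the maximum.
    isodose_level
        Prescription isodose level ID in percent (marginal style only);
        the study sweep uses 60/70/80 but any value in [60, 80] is accepted.
    plateau_radius
        Radius R50 (mm) of the sigmoid shoulder midpoint.  Used directly for
        the point style; for the marginal style it is solved from the
        normalisation and this field is ignored.
    penumbra_width
        Sigmoid shoulder scale w (mm); the stand-in for density-driven
        lateral scatter.
    core_gradient
        Fractional dose drop per mm from the isocenter outward (point style).
    """

    prescription_style: Literal["point", "marginal"]
    isodose_level: float | None = None
    plateau_radius: float = 28.0
    penumbra_width: float = 4.0
    core_gradient: float = 0.003

    def __post_init__(self) -> None:
        if self.prescription_style not in ("point", "marginal"):
            raise ValueError("prescription_style must be 'point' or 'marginal'")
        if self.penumbra_width <= 0:
            raise ValueError("penumbra_width must be > 0")
        if self.prescription_style == "marginal":
            if self.isodose_level is None:
                raise ValueError("marginal style requires an isodose_level")
            if not 60.0 <= float(self.isodose_level) <= 80.0:
                raise ValueError("isodose_level must lie in [60, 80] percent")
        else:
            if self.core_gradient < 0:
                raise ValueError("core_gradient must be >= 0")
            if self.plateau_radius <= 0:
                raise ValueError("plateau_radius must be > 0")

    @property
    def effective_penumbra(self) -> float:
        """Shoulder width actually used: w·(80/ID)^3 for marginal, w for point."""
        if self.prescription_style == "marginal":
            return self.penumbra_width * (
                REFERENCE_ISODOSE / float(self.isodose_level)
            ) ** ID_FALLOFF_EXPONENT
        return self.penumbra_width


@dataclass
class DoseGrid:
    """A scalar dose-like field on a regular grid.

    ``quantity`` records whether the voxel values are total physical dose or
    biologically effective dose (both in Gy).
    """

    values: np.ndarray
    grid: GridSpec
    quantity: Literal["physical", "bed"] = "physical"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise ValueError(
                f"values shape {self.values.shape} != grid shape {self.grid.shape}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("dose values must be finite")
        if np.any(self.values < 0):
            raise ValueError("dose values must be non-negative")
        if self.quantity not in ("physical", "bed"):
            raise ValueError("quantity must be 'physical' or 'bed'")


# ---------------------------------------------------------------------------
# Phantom construction
# ---------------------------------------------------------------------------


def make_phantom(
    spec: PhantomSpec,
    grid: GridSpec,
    center: tuple[float, float, float] = (0.0, 0.0, 0.0),
) -> dict[str, SphereStructure]:
    """Build the concentric GTV/CTV/PTV spheres of the phantom.

    Raises ``ValueError`` if the grid cannot contain the PTV, naming the
    required extent.
    """
    if not grid.contains_sphere(center, spec.ptv_radius):
        raise ValueError(
            f"grid too small: PTV of radius {spec.ptv_radius} mm at {center} "
            f"requires voxel-center bounds covering at least "
            f"{[tuple(c + s * spec.ptv_radius for s in (-1, 1)) for c in center]}, "
            f"grid bounds are {grid.bounds()}"
        )
    return {
        "GTV": SphereStructure(center, spec.gtv_radius, "GTV"),
        "CTV": SphereStructure(center, spec.ctv_radius, "CTV"),
        "PTV": SphereStructure(center, spec.ptv_radius, "PTV"),
    }


def coverage_radius(
    structure: SphereStructure, grid: GridSpec, q: float = 0.95
) -> float:
    """Radius of the voxel that determines the structure's Dq quantile.

    For a radially non-increasing dose, D_q of the structure equals the dose
    at the m-th *smallest* voxel-center radius, m = ceil(q·N) (voxel-count
    convention, no volume interpolation).
    """
    idx = structure.indices(grid)
    if idx.size == 0:
        raise ValueError(f"structure {structure.label} is empty on this grid")
    rho = grid.radial_distance(structure.center).ravel()[idx]
    m = int(math.ceil(q * rho.size))
    return float(np.sort(rho)[m - 1])


# ---------------------------------------------------------------------------
# Dose generation
# ---------------------------------------------------------------------------


def _shoulder(rho: np.ndarray, r50: float, width: float) -> np.ndarray:
    """Sigmoid shoulder Φ((R50−ρ)/w), normalised to 1 at ρ=0."""
    return ndtr((r50 - rho) / width) / ndtr(r50 / width)


def _solve_marginal_r50(r95: float, width: float, id_fraction: float) -> float:
    """Find R50 such that the dose at radius r95 is id_fraction of the maximum."""

    def f(r50: float) -> float:
        return _shoulder(np.asarray(r95), r50, width).item() - id_fraction

    lo, hi = 1e-9, r95 + 20.0 * width
    if f(lo) > 0.0:
        raise NormalizationError(
            f"penumbra width {width:.3g} mm is too wide relative to the PTV "
            f"coverage radius {r95:.3g} mm: the prescription surface cannot sit "
            f"at {100 * id_fraction:.3g}% of the maximum dose"
        )
    if f(hi) < 0.0:  # pragma: no cover - f(hi) -> 1 - id_fraction > 0
        raise NormalizationError("no shoulder midpoint satisfies the normalisation")
    return float(brentq(f, lo, hi, xtol=1e-10))


def generate_dose(
    params: DoseProfileParams,
    structures: Mapping[str, SphereStructure],
    grid: GridSpec,
    prescription_dose: float,
) -> DoseGrid:
    """Generate a radially symmetric, monotone physical dose distribution.

    Normalisation contract:

    * point style — the dose at the voxel closest to the sphere center equals
      ``prescription_dose`` exactly;
    * marginal style — PTV D95% equals ``prescription_dose`` (voxel-count
      convention, exact by construction) and the maximum dose is
      ``prescription_dose × 100 / isodose_level``.
    """
    if prescription_dose <= 0:
        raise ValueError("prescription_dose must be > 0")
    ptv = structures["PTV"]
    if not grid.contains_sphere(ptv.center, ptv.radius):
        raise ValueError("grid too small: PTV not contained in grid")
    rho = grid.radial_distance(ptv.center)

    if params.prescription_style == "point":
        core = np.clip(1.0 - params.core_gradient * rho, 0.0, None)
        rel = core * _shoulder(rho, params.plateau_radius, params.penumbra_width)
        # normalise at the exact center voxel (closest voxel to the center)
        center_rel = rel.ravel()[int(np.argmin(rho.ravel()))]
        if center_rel <= 0:
            raise NormalizationError("center voxel receives zero dose")
        values = prescription_dose * rel / center_rel
    else:
        id_fraction = float(params.isodose_level) / 100.0
        width = params.effective_penumbra
        r95 = coverage_radius(ptv, grid, q=0.95)
        r50 = _solve_marginal_r50(r95, width, id_fraction)
        d_max = prescription_dose / id_fraction
        values = d_max * _shoulder(rho, r50, width)

    return DoseGrid(values, grid, "physical")


def density_to_penumbra(density: float) -> float:
    """Map electron density (g/cm^3) to a penumbra width (mm).

    Exponential decay through the anchors w(1.0)=4 mm and w(0.4)=8 mm —
    strictly decreasing and positive on all of (0, 2].  Lower density means
    longer lateral electron range in lung, hence a broader shoulder.  The
    anchors are module defaults emulating the qualitative effect, not
    measured values.
    """
    if not 0 < density <= 2:
        raise ValueError("density must lie in (0, 2] g/cm^3")
    (rho_hi, w_hi), (rho_lo, w_lo) = PENUMBRA_ANCHOR_HIGH, PENUMBRA_ANCHOR_LOW
    rate = math.log(w_lo / w_hi) / (rho_hi - rho_lo)
    return w_hi * math.exp(rate * (rho_hi - density))


# ---------------------------------------------------------------------------
# Grid I/O
# ---------------------------------------------------------------------------
#
# Preferred format: NRRD via SimpleITK, with the stored quantity recorded in
# the key-value metadata under ``dosimargin.quantity``.  Fallback format
# (documented bit-exactly): a JSON header ``<stem>.json`` holding shape,
# spacing, origin, quantity, dtype "<f4" and index order "C (x,y,z)", next to
# a raw file ``<stem>.raw`` of little-endian float32 voxel values in C order.


def _sitk():
    import SimpleITK as sitk

    return sitk


def write_dose_grid(dose: DoseGrid, path: str | Path) -> None:
    """Write a dose grid to ``.nrrd`` (preferred) or ``.json``+``.raw``."""
    path = Path(path)
    if path.suffix == ".json":
        header = {
            "shape": list(dose.grid.shape),
            "spacing": list(dose.grid.spacing),
            "origin": list(dose.grid.origin),
            "quantity": dose.quantity,
            "dtype": "<f4",
            "order": "C (x,y,z)",
        }
        path.write_text(json.dumps(header, indent=2, sort_keys=True))
        path.with_suffix(".raw").write_bytes(
            np.ascontiguousarray(dose.values, dtype="<f4").tobytes()
        )
        return
    sitk = _sitk()
    img = sitk.GetImageFromArray(np.ascontiguousarray(dose.values.transpose(2, 1, 0)))
    img.SetSpacing(tuple(dose.grid.spacing))
    img.SetOrigin(tuple(dose.grid.origin))
    img.SetMetaData(QUANTITY_KEY, dose.quantity)
    sitk.WriteImage(img, str(path), useCompression=False)


def read_dose_grid(path: str | Path) -> DoseGrid:
    """Read a dose grid written by :func:`write_dose_grid` (or any NRRD)."""
    path = Path(path)
    if path.suffix == ".json":
        header = json.loads(path.read_text())
        grid = GridSpec(
            tuple(header["shape"]), tuple(header["spacing"]), tuple(header["origin"])
        )
        values = np.frombuffer(
            path.with_suffix(".raw").read_bytes(), dtype="<f4"
        ).reshape(grid.shape)
        return DoseGrid(values.astype(float), grid, header.get("quantity", "physical"))
    sitk = _sitk()
    img = sitk.ReadImage(str(path))
    values = sitk.GetArrayFromImage(img).transpose(2, 1, 0).astype(float)
    grid = GridSpec(values.shape, tuple(img.GetSpacing()), tuple(img.GetOrigin()))
    quantity = "physical"
    if img.HasMetaDataKey(QUANTITY_KEY):
        quantity = img.GetMetaData(QUANTITY_KEY)
    return DoseGrid(values, grid, quantity)


def write_structure_mask(
    structure: SphereStructure, grid: GridSpec, path: str | Path
) -> None:
    """Export a structure as a binary (0/1) mask in the same grid formats."""
    path = Path(path)
    mask = structure.mask(grid)
    if path.suffix == ".json":
        header = {
            "shape": list(grid.shape),
            "spacing": list(grid.spacing),
            "origin": list(grid.origin),
            "label": structure.label,
            "dtype": "u1",
            "order": "C (x,y,z)",
        }
        path.write_text(json.dumps(header, indent=2, sort_keys=True))
        path.with_suffix(".raw").write_bytes(mask.astype(np.uint8).tobytes())
        return
    sitk = _sitk()
    img = sitk.GetImageFromArray(
        np.ascontiguousarray(mask.transpose(2, 1, 0).astype(np.uint8))
    )
    img.SetSpacing(tuple(grid.spacing))
    img.SetOrigin(tuple(grid.origin))
    img.SetMetaData("dosimargin.label", structure.label)
    sitk.WriteImage(img, str(path), useCompression=False)
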