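"""DVH quantiles, isocenter-shift scans and dosimetric margins.

The dosimetric margin quantifies how far the isocenter can be displaced
before target coverage is lost: the CTV's D95% must stay at or above 90% of
the prescribed quantity.  Evaluated on the physical dose this yields the
physical dosimetric margin (PDM); evaluated on the BED grid against the
prescribed BED it yields the biological dosimetric margin (BDM).

Shifts are scanned along one cardinal axis at a time, from 0 outward to
±shift_range in shift_step increments (the study convention: ±20 mm, 1 mm).
A shift is realised by translating the CTV sphere and re-rasterising it
analytically at the shifted center, which avoids any interpolation of the
dose field.  The per-sign acceptance extent is the largest scanned shift such
that the coverage criterion holds at *every* intermediate scanned shift
(contiguity guard); the margin is the minimum of the two extents.  Optional
sub-step linear interpolation of the D95-vs-shift curve at the crossing can
refine the extents.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd

from .bed_model import FractionationScheme, RadiobiologyParams, physical_to_bed, prescribed_bed
from .synthetic_dose import AXES, DoseGrid, SphereStructure

__all__ = [
    "CoverageCriterion",
    "ShiftAcceptanceProfile",
    "MarginResult",
    "MarginPair",
    "dvh_quantile",
    "shifted_d95",
    "dosimetric_margin",
    "margin_pair",
    "profile_to_frame",
    "margins_to_frame",
]


@dataclass(frozen=True)
class CoverageCriterion:
    """Coverage test D_{quantile} >= threshold_fraction × prescribed value.

    Defaults are the study convention: D95% >= 90%, shifts scanned over
    ±20 mm in 1-mm steps, no sub-step interpolation.
    """

    quantile: float = 0.95
    threshold_fraction: float = 0.90
    shift_range: float = 20.0
    shift_step: float = 1.0
    interpolate: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.quantile < 1:
            raise ValueError("quantile must lie in (0, 1)")
        if not 0 < self.threshold_fraction <= 1:
            raise ValueError("threshold_fraction must lie in (0, 1]")
        if self.shift_step <= 0:
            raise ValueError("shift_step must be > 0")
        if self.shift_range < self.shift_step:
            raise ValueError("shift_range must be >= shift_step")

    @property
    def n_steps(self) -> int:
        return int(math.floor(self.shift_range / self.shift_step + 1e-9))


@dataclass(frozen=True)
class ShiftAcceptanceProfile:
    """D95 and acceptance flag at every scanned shift along one axis."""

    axis: str
    shifts: np.ndarray
    d95_values: np.ndarray
    accepted: np.ndarray
    threshold: float

    def __post_init__(self) -> None:
        shifts = np.asarray(self.shifts, dtype=float)
        d95 = np.asarray(self.d95_values, dtype=float)
        acc = np.asarray(self.accepted, dtype=bool)
        if not (len(shifts) == len(d95) == len(acc)):
            raise ValueError("profile arrays must have equal length")
        if np.any(np.diff(shifts) <= 0):
            raise ValueError("shifts must be strictly increasing")
        object.__setattr__(self, "shifts", shifts)
        object.__setattr__(self, "d95_values", d95)
        object.__setattr__(self, "accepted", acc)


@dataclass(frozen=True)
class MarginResult:
    """Per-axis dosimetric margin with the acceptance extents behind it."""

    axis: str
    margin_mm: float
    positive_extent_mm: float
    negative_extent_mm: float
    quantity: str
    interpolated: bool = False
    status: str = "ok"  # "ok" or "failed_at_zero"
    profile: ShiftAcceptanceProfile | None = field(default=None, compare=False)


class MarginPair(NamedTuple):
    pdm: MarginResult
    bdm: MarginResult


# ---------------------------------------------------------------------------
# DVH quantile
# ---------------------------------------------------------------------------


def dvh_quantile(dose: DoseGrid, mask, q: float) -> float:
    """Dose covering fraction ``q`` of the masked voxels.

    Returns the largest dose D such that at least ``q·N`` masked voxels
    receive >= D: with doses sorted descending this is the ``ceil(q·N)``-th
    value.  Pure voxel-count convention, no binning and no volume
    interpolation.
    """
    if not 0 < q <= 1:
        raise ValueError("q must lie in (0, 1]")
    if isinstance(mask, SphereStructure):
        vals = dose.values.ravel()[mask.indices(dose.grid)]
    else:
        vals = dose.values[np.asarray(mask, dtype=bool)]
    if vals.size == 0:
        raise ValueError("empty mask: DVH quantile undefined")
    m = int(math.ceil(q * vals.size))
    return float(np.sort(vals.ravel())[::-1][m - 1])


def shifted_d95(
    dose: DoseGrid,
    ctv: SphereStructure,
    shift: tuple[float, float, float],
    q: float = 0.95,
) -> float:
    """D_q of the CTV under an isocenter shift.

    Shifting the isocenter by ``+shift`` is realised as translating the
    structure by ``−shift`` over the fixed dose grid; the structure sphere is
    re-rasterised analytically at the shifted center.
    """
    moved = ctv.translated(tuple(-s for s in shift))
    if not dose.grid.contains_sphere(moved.center, moved.radius):
        raise ValueError(
            f"shifted structure (center {moved.center}, radius {moved.radius}) "
            f"exits the grid bounds {dose.grid.bounds()}"
        )
    return dvh_quantile(dose, moved, q)


# ---------------------------------------------------------------------------
# Margin scan
# ---------------------------------------------------------------------------


def _axis_index(axis: str) -> int:
    try:
        return AXES.index(axis)
    except ValueError:
        raise ValueError(f"axis must be one of {AXES}, got {axis!r}") from None


def _extent(
    shifts: np.ndarray,
    d95: np.ndarray,
    accepted: np.ndarray,
    threshold: float,
    step: float,
    interpolate: bool,
) -> float:
    """Contiguous acceptance extent along one sign of the scan.

    ``shifts``/``d95``/``accepted`` are ordered outward from shift 0
    (inclusive).  Acceptance must hold at every intermediate scanned shift.
    """
    k = 0
    while k + 1 < len(shifts) and accepted[k + 1]:
        k += 1
    extent = abs(shifts[k])
    if interpolate and k + 1 < len(shifts):
        lo, hi = d95[k], d95[k + 1]
        if lo > threshold and lo > hi:
            frac = (lo - threshold) / (lo - hi)
            extent += step * min(max(frac, 0.0), 1.0)
    return float(extent)


def dosimetric_margin(
    dose: DoseGrid,
    ctv: SphereStructure,
    axis: str,
    criterion: CoverageCriterion,
    prescribed_value: float,
) -> MarginResult:
    """Scan isocenter shifts along ``axis`` and derive the dosimetric margin.

    The margin is ``min(positive_extent, negative_extent)`` of the contiguous
    acceptance extents.  If the criterion already fails at zero shift the
    margin is 0 with status ``"failed_at_zero"``.
    """
    if prescribed_value <= 0:
        raise ValueError("prescribed_value must be > 0")
    iax = _axis_index(axis)
    threshold = criterion.threshold_fraction * prescribed_value
    n = criterion.n_steps
    shifts = criterion.shift_step * np.arange(-n, n + 1)
    d95 = np.empty_like(shifts)
    for i, s in enumerate(shifts):
        vec = [0.0, 0.0, 0.0]
        vec[iax] = float(s)
        d95[i] = shifted_d95(dose, ctv, tuple(vec), criterion.quantile)
    accepted = d95 >= threshold
    profile = ShiftAcceptanceProfile(axis, shifts, d95, accepted, threshold)

    i0 = n  # index of zero shift
    if not accepted[i0]:
        return MarginResult(
            axis, 0.0, 0.0, 0.0, dose.quantity, criterion.interpolate,
            "failed_at_zero", profile,
        )
    pos = _extent(
        shifts[i0:], d95[i0:], accepted[i0:], threshold,
        criterion.shift_step, criterion.interpolate,
    )
    neg = _extent(
        shifts[i0::-1], d95[i0::-1], accepted[i0::-1], threshold,
        criterion.shift_step, criterion.interpolate,
    )
    return MarginResult(
        axis, min(pos, neg), pos, neg, dose.quantity,
        criterion.interpolate, "ok", profile,
    )


def margin_pair(
    physical: DoseGrid,
    ctv: SphereStructure,
    scheme: FractionationScheme,
    rb: RadiobiologyParams,
    criterion: CoverageCriterion,
    axis: str,
    prescription_dose: float,
) -> MarginPair:
    """PDM from the physical grid and BDM from its BED conversion.

    The PDM criterion references the physical prescription dose; the BDM
    criterion references the prescribed BED of the scheme.
    """
    pdm = dosimetric_margin(physical, ctv, axis, criterion, prescription_dose)
    bed = physical_to_bed(physical, scheme, rb, prescription_dose)
    bdm = dosimetric_margin(bed, ctv, axis, criterion, prescribed_bed(scheme, rb))
    return MarginPair(pdm, bdm)


# ---------------------------------------------------------------------------
# Tabular export
# ---------------------------------------------------------------------------


def profile_to_frame(profile: ShiftAcceptanceProfile) -> pd.DataFrame:
    """Acceptance profile as a table: axis, shift_mm, d95, accepted."""
    return pd.DataFrame(
        {
            "axis": profile.axis,
            "shift_mm": profile.shifts,
            "d95": profile.d95_values,
            "accepted": profile.accepted,
        }
    )


def margins_to_frame(results: list[MarginResult]) -> pd.DataFrame:
    """Margins as a table: axis, quantity, margin_mm, pos_extent, neg_extent."""
    return pd.DataFrame(
        {
            "axis": [r.axis for r in results],
            "quantity": [r.quantity for r in results],
            "margin_mm": [r.margin_mm for r in results],
            "pos_extent": [r.positive_extent_mm for r in results],
            "neg_extent": [r.negative_extent_mm for r in results],
        }
    )
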