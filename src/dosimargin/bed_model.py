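"""Linear-quadratic biologically effective dose (BED) conversion.

The LQ model summarises the biological impact of ``n`` fractions of ``d`` Gy
as ``BED = n d (1 + d / (α/β))``, where α/β (Gy) is the dose at which the
linear and quadratic components of cell kill are equal (≈10 Gy for tumors,
≈3 Gy for late-reacting normal tissue).

A heterogeneous physical dose grid is converted voxel-wise: the plan is first
rescaled so the prescription metric carries the evaluated scheme's total dose
``n·d``, every voxel then receives its dose in the same ``n`` fractions, and
the scalar LQ formula is applied per voxel.  Because a voxel at relative dose
r < 1 has relative BED r·(1 + r d/(α/β))/(1 + d/(α/β)) < r, BED distributions
are "contracted" below the prescription level — the mechanism that makes
biological margins smaller than physical ones at hypofractionated doses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .synthetic_dose import DoseGrid

__all__ = [
    "FractionationScheme",
    "RadiobiologyParams",
    "bed_scalar",
    "prescribed_bed",
    "physical_to_bed",
]


@dataclass(frozen=True)
class FractionationScheme:
    """``n`` fractions of ``d`` Gy per fraction."""

    n: int
    d: float

    def __post_init__(self) -> None:
        if int(self.n) != self.n or self.n < 1:
            raise ValueError("fraction count n must be an integer >= 1")
        object.__setattr__(self, "n", int(self.n))
        if self.d <= 0:
            raise ValueError("dose per fraction d must be > 0")

    @property
    def total_dose(self) -> float:
        return self.n * self.d

    def label(self) -> str:
        d = f"{self.d:g}"
        return f"{d}Gy x {self.n}"


@dataclass(frozen=True)
class RadiobiologyParams:
    """Radiobiological inputs of the LQ model (currently just α/β, Gy)."""

    alpha_beta: float

    def __post_init__(self) -> None:
        if self.alpha_beta <= 0:
            raise ValueError("alpha_beta must be > 0")


def bed_scalar(n: int, d: float, alpha_beta: float) -> float:
    """BED of ``n`` uniform fractions of ``d`` Gy: ``n d (1 + d/(α/β))``."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if d < 0:
        raise ValueError("d must be >= 0")
    if alpha_beta <= 0:
        raise ValueError("alpha_beta must be > 0")
    return n * d * (1.0 + d / alpha_beta)


def prescribed_bed(scheme: FractionationScheme, rb: RadiobiologyParams) -> float:
    """BED delivered at the prescription level (the 100% BED reference)."""
    return bed_scalar(scheme.n, scheme.d, rb.alpha_beta)


def physical_to_bed(
    dose: DoseGrid,
    scheme: FractionationScheme,
    rb: RadiobiologyParams,
    prescription_dose: float,
) -> DoseGrid:
    """Convert a physical dose grid to BED for one fractionation scheme.

    Each voxel's total dose is rescaled by ``n·d / prescription_dose`` (so the
    prescription metric carries the scheme's total dose), split into ``n``
    equal fractions ``d_v``, and mapped to ``n d_v (1 + d_v/(α/β))``.
    """
    if dose.quantity != "physical":
        raise ValueError(f"expected a physical dose grid, got quantity={dose.quantity!r}")
    if prescription_dose <= 0:
        raise ValueError("prescription_dose must be > 0")
    rel = dose.values / prescription_dose
    d_v = rel * scheme.d  # per-fraction voxel dose after rescaling
    values = scheme.n * d_v * (1.0 + d_v / rb.alpha_beta)
    return DoseGrid(np.asarray(values), dose.grid, "bed")
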