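"""Full study sweep: styles × isodose levels × schemes × axes × densities.

For every prescription style (point, marginal at 60/70/80%) and tumor
density, one synthetic dose distribution is generated and the per-axis PDM is
measured once (the PDM does not depend on the fractionation scheme, because
the BED rescaling cancels in the 90%-relative criterion).  For every
fractionation scheme and α/β the grid is converted to BED and the per-axis
BDM is measured; each (style, scheme, axis) yields one BCF sample.

Headline fits follow the study design: BCF samples at the tumor α/β (10 Gy)
and the reference density (1.0 g/cm³), all three cardinal directions pooled
as separate samples.  The α/β = 3 Gy rows are computed for completeness but
excluded from the headline fits; the density sweep feeds the robustness
report instead.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .bcf_model import BCFFit, BCFSample, fit_bcf, pooled_bcf_stats
from .bed_model import FractionationScheme, RadiobiologyParams, physical_to_bed, prescribed_bed
from .margin_engine import CoverageCriterion, MarginResult, dosimetric_margin
from .synthetic_dose import (
    AXES,
    DoseProfileParams,
    GridSpec,
    PhantomSpec,
    density_to_penumbra,
    generate_dose,
    make_phantom,
)

__all__ = [
    "DEFAULT_SCHEMES",
    "StudyConfig",
    "StudyResult",
    "run_study",
    "density_robustness_report",
    "write_outputs",
]

logger = logging.getLogger("dosimargin")

#: The 11 fractionation schemes of the study sweep, (n fractions, d Gy).
DEFAULT_SCHEMES: tuple[FractionationScheme, ...] = tuple(
    FractionationScheme(n, d)
    for n, d in [
        (15, 3.0),
        (10, 5.0),
        (10, 6.0),
        (5, 7.0),
        (8, 7.5),
        (3, 8.0),
        (5, 10.0),
        (4, 12.0),
        (3, 15.0),
        (3, 18.0),
        (3, 20.0),
    ]
)

#: Default style sweep: point prescription plus marginal at 60/70/80%.
DEFAULT_STYLES: tuple[tuple[str, float | None], ...] = (
    ("point", None),
    ("marginal", 60.0),
    ("marginal", 70.0),
    ("marginal", 80.0),
)


@dataclass(frozen=True)
class StudyConfig:
    """Everything that determines a study run (deterministic given this)."""

    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    grid: GridSpec = field(default_factory=GridSpec.centered)
    criterion: CoverageCriterion = field(
        default_factory=lambda: CoverageCriterion(interpolate=True)
    )
    schemes: tuple[FractionationScheme, ...] = DEFAULT_SCHEMES
    alpha_betas: tuple[float, ...] = (10.0, 3.0)
    styles: tuple[tuple[str, float | None], ...] = DEFAULT_STYLES
    densities: tuple[float, ...] = (0.4, 0.7, 1.0)
    prescription_dose: float = 48.0
    headline_alpha_beta: float = 10.0
    baseline_density: float = 1.0
    point_plateau_radius: float = 28.0
    point_core_gradient: float = 0.003
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not self.schemes:
            raise ValueError("schemes must be non-empty")
        if not self.styles:
            raise ValueError("at least one prescription style is required")
        if self.prescription_dose <= 0:
            raise ValueError("prescription_dose must be > 0")

    @classmethod
    def from_dict(cls, data: Mapping) -> "StudyConfig":
        kw = dict(data)
        if "phantom" in kw:
            kw["phantom"] = PhantomSpec(**kw["phantom"])
        if "grid" in kw:
            g = kw["grid"]
            kw["grid"] = (
                GridSpec.centered(**g)
                if "half_extent" in g or "spacing" in g and "shape" not in g
                else GridSpec(tuple(g["shape"]), tuple(g["spacing"]), tuple(g["origin"]))
            )
        if "criterion" in kw:
            kw["criterion"] = CoverageCriterion(**kw["criterion"])
        if "schemes" in kw:
            kw["schemes"] = tuple(FractionationScheme(int(n), float(d)) for n, d in kw["schemes"])
        if "styles" in kw:
            kw["styles"] = tuple(
                (s, None) if i is None else (s, float(i)) for s, i in kw["styles"]
            )
        for name in ("alpha_betas", "densities"):
            if name in kw:
                kw[name] = tuple(float(v) for v in kw[name])
        return cls(**kw)

    @classmethod
    def from_file(cls, path: str | Path) -> "StudyConfig":
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls.from_dict(data or {})


@dataclass
class StudyResult:
    """Sweep table, headline BCF fits, samples and pooled statistics."""

    table: pd.DataFrame
    fits: dict[str, BCFFit]
    samples: pd.DataFrame
    pooled: pd.DataFrame
    config: StudyConfig


def _style_params(config: StudyConfig, style: str, idl: float | None, width: float) -> DoseProfileParams:
    return DoseProfileParams(
        prescription_style=style,
        isodose_level=idl,
        plateau_radius=config.point_plateau_radius,
        penumbra_width=width,
        core_gradient=config.point_core_gradient,
    )


def _style_label(style: str, idl: float | None) -> str:
    return style if idl is None else f"{style}{idl:g}"


def run_study(config: StudyConfig) -> StudyResult:
    """Run the full sweep and fit the point and marginal BCF models.

    One row per (density, style, scheme, α/β, axis); PDM is computed once per
    (density, style, axis) and repeated across scheme rows.  Deterministic
    for a given config.
    """
    structures = make_phantom(config.phantom, config.grid)
    ctv = structures["CTV"]
    rows: list[dict] = []
    t_start = time.perf_counter()

    for density in config.densities:
        width = density_to_penumbra(density)
        for style, idl in config.styles:
            label = _style_label(style, idl)
            t0 = time.perf_counter()
            params = _style_params(config, style, idl, width)
            try:
                dose = generate_dose(params, structures, config.grid, config.prescription_dose)
                pdm: dict[str, MarginResult] = {
                    axis: dosimetric_margin(
                        dose, ctv, axis, config.criterion, config.prescription_dose
                    )
                    for axis in AXES
                }
                for ab in config.alpha_betas:
                    rb = RadiobiologyParams(ab)
                    for scheme in config.schemes:
                        bed = physical_to_bed(dose, scheme, rb, config.prescription_dose)
                        ref_bed = prescribed_bed(scheme, rb)
                        for axis in AXES:
                            bdm = dosimetric_margin(bed, ctv, axis, config.criterion, ref_bed)
                            rows.append(
                                {
                                    "style": label,
                                    "id_percent": idl if idl is not None else np.nan,
                                    "n_fractions": scheme.n,
                                    "dose_per_fraction": scheme.d,
                                    "alpha_beta": ab,
                                    "axis": axis,
                                    "density": density,
                                    "pdm_mm": pdm[axis].margin_mm,
                                    "bdm_mm": bdm.margin_mm,
                                    "bcf": bdm.margin_mm / pdm[axis].margin_mm,
                                }
                            )
            except Exception as exc:
                # flush what we have so the failing combination is identifiable
                raise RuntimeError(
                    f"study stage failed at density={density}, style={label}: {exc}"
                ) from exc
            logger.info(
                "swept density=%.2g style=%s in %.2fs", density, label, time.perf_counter() - t0
            )

    table = pd.DataFrame(rows)

    headline = table[
        (table["alpha_beta"] == config.headline_alpha_beta)
        & (table["density"] == config.baseline_density)
    ]
    samples = headline.copy()
    samples["d_over_ab"] = samples["dose_per_fraction"] / samples["alpha_beta"]

    fits: dict[str, BCFFit] = {}
    point_rows = samples[samples["style"] == "point"]
    if len(point_rows) >= 2 and point_rows["d_over_ab"].nunique() >= 2:
        fits["point"] = fit_bcf(
            [
                BCFSample(r.d_over_ab, r.bcf, r.axis, None, r.density)
                for r in point_rows.itertuples()
            ],
            "point",
        )
    marginal_rows = samples[samples["style"] != "point"]
    if (
        len(marginal_rows) >= 4
        and marginal_rows["id_percent"].nunique() >= 2
        and marginal_rows["d_over_ab"].nunique() >= 2
    ):
        fits["marginal"] = fit_bcf(
            [
                BCFSample(r.d_over_ab, r.bcf, r.axis, r.id_percent, r.density)
                for r in marginal_rows.itertuples()
            ],
            "marginal",
        )

    if len(samples):
        pooled = pooled_bcf_stats(
            [
                BCFSample(
                    r.d_over_ab,
                    r.bcf,
                    r.axis,
                    None if np.isnan(r.id_percent) else r.id_percent,
                    r.density,
                )
                for r in samples.itertuples()
            ]
        )
    else:
        pooled = pd.DataFrame(columns=["id_percent", "d_over_ab", "mean", "sem", "n"])
    logger.info("study sweep finished in %.2fs (%d rows)", time.perf_counter() - t_start, len(table))
    return StudyResult(table, fits, samples, pooled, config)


def density_robustness_report(result: StudyResult) -> pd.DataFrame:
    """Deviation of the BCF from the baseline density, against its SEM.

    For each style/scheme (headline α/β): the direction-averaged BCF per
    density, its absolute deviation from the baseline-density value, and the
    SEM of the baseline group across directions; ``within_sem`` flags
    deviations not exceeding that SEM.
    """
    cfg = result.config
    t = result.table
    t = t[t["alpha_beta"] == cfg.headline_alpha_beta]
    if cfg.baseline_density not in set(t["density"].unique()):
        raise ValueError(f"baseline density {cfg.baseline_density} missing from results")
    if t["density"].nunique() < 2:
        raise ValueError("density robustness report needs >= 2 densities")

    keys = ["style", "n_fractions", "dose_per_fraction"]
    mean_bcf = t.groupby(keys + ["density"])["bcf"].mean().reset_index(name="bcf_mean")
    base = t[t["density"] == cfg.baseline_density]
    base_mean = base.groupby(keys)["bcf"].mean().rename("bcf_baseline")
    base_sem = (
        base.groupby(keys)["bcf"]
        .agg(lambda v: v.std(ddof=1) / np.sqrt(len(v)) if len(v) > 1 else np.nan)
        .rename("sem_baseline")
    )
    out = mean_bcf.join(base_mean, on=keys).join(base_sem, on=keys)
    out["abs_dev"] = (out["bcf_mean"] - out["bcf_baseline"]).abs()
    out["within_sem"] = out["abs_dev"] <= out["sem_baseline"]
    return out.sort_values(keys + ["density"]).reset_index(drop=True)


def write_outputs(result: StudyResult, out_dir: str | Path) -> dict[str, Path]:
    """Write margins.csv, bcf_samples.csv, fits.json (+ density_report.csv).

    Columns — margins.csv: style, id_percent, n_fractions, dose_per_fraction,
    alpha_beta, axis, density, pdm_mm, bdm_mm, bcf (one row per swept
    combination).  bcf_samples.csv: the headline-fit samples with d_over_ab.
    fits.json: {style: {style, params, sd, n}}.  density_report.csv: output
    of :func:`density_robustness_report` when >= 2 densities were swept.
    All floats use repr-exact formatting so identical configs give
    byte-identical files.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["margins"] = out_dir / "margins.csv"
    result.table.to_csv(paths["margins"], index=False, float_format="%.12g")

    paths["bcf_samples"] = out_dir / "bcf_samples.csv"
    cols = [
        "style", "id_percent", "direction", "d_over_ab", "bcf", "density",
    ]
    samples = result.samples.rename(columns={"axis": "direction"})[
        ["style", "id_percent", "direction", "d_over_ab", "bcf", "density"]
    ]
    samples.columns = cols
    samples.to_csv(paths["bcf_samples"], index=False, float_format="%.12g")

    paths["fits"] = out_dir / "fits.json"
    fits_obj = {name: fit.as_dict() for name, fit in sorted(result.fits.items())}
    paths["fits"].write_text(json.dumps(fits_obj, indent=2, sort_keys=True) + "\n")

    if result.table["density"].nunique() >= 2:
        paths["density_report"] = out_dir / "density_report.csv"
        density_robustness_report(result).to_csv(
            paths["density_report"], index=False, float_format="%.12g"
        )
    return paths
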