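# Methods

## Scope and pipeline

The package computes physical and biological dosimetric margins (PDM/BDM)
and the biological conversion factor (BCF = BDM/PDM) on synthetic SBRT dose
distributions. The pipeline runs in four stages:

1. **Phantom & dose generation** (`synthetic_dose`) — concentric GTV/CTV/PTV
   spheres (defaults 10 / 10 / 15 mm) on a regular grid, plus a radially
   symmetric parametric dose field per prescription style.
2. **BED conversion** (`bed_model`) — voxel-wise linear-quadratic mapping per
   fractionation scheme and α/β.
3. **Margin derivation** (`margin_engine`) — isocenter-shift scan under the
   D95% ≥ 90% coverage criterion, per cardinal axis.
4. **BCF modelling** (`bcf_model`, `study_pipeline`) — BCF samples across the
   scheme sweep, pooled over directions, fitted by exact least squares.

## Dose model

There is no beam transport here: dose fields are analytic stand-ins chosen
to reproduce the *gradient structure* that separates the two prescription
styles, with as few knobs as possible.

All profiles are monotone non-increasing functions of the distance ρ from
the tumor center, built from a normal-CDF shoulder
`S(ρ) = Φ((R50 − ρ)/w) / Φ(R50/w)` (so `S(0) = 1`).

* **Point (isocenter) prescription** — `D(ρ) = Rx · (1 − g·ρ)₊ · S(ρ)`,
  normalised to the prescription dose `Rx` at the exact center voxel.
  The linear core gradient `g` (default 0.003 /mm) gives the shallow
  through-target falloff of a 3D-CRT plan; the shoulder midpoint `R50`
  (default 28 mm) and width `w` terminate the field.
* **Marginal prescription** — `D(ρ) = (Rx·100/ID) · S(ρ)` with `R50` solved
  (Brent root-finding) so that the dose at the PTV's D95-determining voxel
  radius equals `Rx` exactly. Both normalisation contracts then hold
  simultaneously: PTV D95% = Rx and maximum dose = Rx·100/ID.

### The isodose-level → falloff-scale coupling

For the marginal style the effective shoulder width is
`w_eff = w · (80/ID)³`. This is a deliberate design choice, not a physics
claim. A *fixed*-shape sigmoid would make the acceptance distance beyond the
prescription surface `w·[Φ⁻¹(ID) − Φ⁻¹(0.9·ID)]`, which **increases** with
ID over 60–80% — the opposite of the empirically observed ordering in which
prescriptions to a lower isodose line (hotter core) carry the larger
margins. Scaling the shoulder width by `(80/ID)³` makes the relative dose
outside the prescription surface dominate pointwise in decreasing ID order
(asserted by test), which yields both the margin ordering
(PDM/BDM at 60% ≥ 70% ≥ 80%) and, downstream, a positive fitted E
coefficient (higher ID sits closer to BCF = 1). The exponent 3 is the
smallest integer that makes the ordering robust at the default penumbra;
it is a module constant (`ID_FALLOFF_EXPONENT`).

### Density stand-in

Tumor/lung electron density enters only through the penumbra width:
`w(ρe) = 4 · 2^((1−ρe)/0.6)` mm, an exponential decay through the anchors
w(1.0 g/cm³) = 4 mm and w(0.4) = 8 mm. An exponential rather than a linear
interpolation keeps the map strictly decreasing *and* positive on the whole
admissible density range (0, 2]; a linear map would cross zero before
2 g/cm³. The anchors are defaults emulating increased lateral scatter in
low-density lung, not measured values.

## BED conversion

`BED = n·d·(1 + d/(α/β))` per voxel, with two conventions:

* **Fraction splitting** — every voxel receives its dose in the same `n`
  fractions (`d_v = D_v/n`); the only reading consistent with a single
  fraction number per scheme.
* **Scheme rescaling** — the relative dose distribution is rescaled so the
  prescription metric carries the evaluated scheme's total dose `n·d`. The
  PDM is then identical for every scheme (the 90%-relative physical
  criterion is scale-free) and only the BDM varies, so each scheme
  contributes exactly one BCF sample per axis.

Defaults follow standard radiobiology: α/β = 10 Gy (tumor) for the headline
analysis, α/β = 3 Gy (late-reacting normal tissue) computed for completeness
but excluded from the headline fits. No EQD2, repopulation or high-dose LQ
corrections.

## Margin derivation

* **DVH convention** — exact voxel-count quantile: D95 is the
  `ceil(0.95·N)`-th largest masked voxel dose. No binning, no volume
  interpolation; removes bin width as a hidden parameter.
* **Shift realisation** — the CTV sphere is translated by −shift and
  re-rasterised analytically (voxel-center-inside rule) at the shifted
  center; the dose grid is never resampled, so no interpolation error enters
  the scan.
* **Extents** — scanned outward from 0 in 1-mm steps to ±20 mm; the per-sign
  extent is the largest shift with the criterion satisfied at *every*
  intermediate scanned shift (contiguity guard against numerical blips); the
  margin is the minimum of the two extents, with both retained in the
  result. If coverage already fails at zero shift the margin is 0 with an
  explicit `failed_at_zero` status.
* **Sub-step interpolation** — `CoverageCriterion(interpolate=True)` refines
  each extent by linear interpolation of the D95-vs-shift curve at the
  threshold crossing. The engine default is off (pure 1-mm scan), but the
  study pipeline enables it: on this idealised isotropic phantom the
  style-to-style margin differences are partly sub-millimeter and would
  quantise to identical integers at 1-mm resolution, collapsing all marginal
  BCFs to exactly 1. Interpolation resolves them without changing any
  ordering (the interpolated extent always lies within one step of the
  scanned one, an asserted property).

## BCF fitting

Both model forms are linear in their parameters given the `ln(d/(α/β))` and
`ID` regressors, so the fit is the exact normal-equations solution — no
iterative optimiser, no initialisation or tolerance knobs. All three
directions enter as separate samples (not averaged first). Parameter
uncertainties use the classical linear-model covariance `σ̂²(XᵀX)⁻¹` with
`σ̂² = RSS/(n−p)`; a seeded nonparametric bootstrap is available as an
alternative. Rank-deficient designs (a single isodose level, a single
abscissa) raise with the deficiency named.

## Study sweep defaults

* 11 fractionation schemes: 3 Gy×15, 5×10, 6×10, 7×5, 7.5×8, 8×3, 10×5,
  12×4, 15×3, 18×3, 20×3 (dose per fraction 3–20 Gy).
* Prescription 48 Gy; styles point + marginal at 60/70/80%.
* Grid: 2 mm isotropic, ±48 mm (49³ voxels) — matching a 2-mm CT
  reconstruction; a 1-mm grid is available for convergence checks.
* Densities 0.4/0.7/1.0 g/cm³; style-to-style comparisons are made at the
  shared reference density 1.0 so they isolate the prescription method.
* Everything is deterministic given the configuration; the seed exists for
  the bootstrap option and future stochastic extensions.

The whole default sweep runs in about a second on one core, so no
scaled-down problem sizes are needed anywhere in the tests.

## What the synthetic phantom does and does not show

The generator reproduces: the monotone radial falloff of an SBRT dose
distribution, the shallow-core/steep-shoulder contrast between point and
marginal prescriptions, the normalisation conventions of both prescription
styles, and the margin orderings that follow from them. It does **not**
model: beam/arc geometry, MLC or collimator effects, heterogeneity-corrected
transport, plan-optimizer trade-offs, anisotropy between axes (the phantom
is exactly isotropic, so the across-direction SEM is ~0 rather than the
small positive spread a real plan shows), rotational or random/respiratory
errors, or normal-tissue margins. Passing tests therefore validate the
margin/BCF *machinery* and the directional claims, not the absolute margin
values of any clinical plan; absolute PDM/BDM in mm depend directly on the
penumbra and core-gradient defaults.

## Known limitations

* The density→penumbra map is a one-knob stand-in; real density effects also
  change the depth-dose and the absolute dose level.
* BCF sensitivity to density is exaggerated relative to a planning system
  (the robustness report's `within_sem` column fails where the idealised
  SEM is ~0).
* Margins are axis-aligned scans only; no 3-D vector-shift margin maps.
* The marginal ID–falloff coupling is calibrated to reproduce an ordering,
  not a measured penumbra difference between 60% and 80% plans.
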