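"""Phantom geometry, dose-profile contracts and grid I/O."""

import math

import numpy as np
import pytest

from dosimargin import (
    DoseProfileParams,
    GridSpec,
    NormalizationError,
    PhantomSpec,
    SphereStructure,
    coverage_radius,
    density_to_penumbra,
    dvh_quantile,
    generate_dose,
    make_phantom,
    read_dose_grid,
    write_dose_grid,
)


class TestPhantom:
    def test_study_radii(self, structures):
        assert structures["GTV"].radius == 10.0
        assert structures["CTV"].radius == 10.0  # CTV margin is 0
        assert structures["PTV"].radius == 15.0

    def test_zero_ctv_margin_gives_identical_masks(self, structures, grid):
        assert np.array_equal(
            structures["GTV"].mask(grid), structures["CTV"].mask(grid)
        )

    def test_ptv_voxel_count_matches_analytic_volume(self):
        grid = GridSpec.centered(half_extent=20.0, spacing=1.0)
        ptv = make_phantom(PhantomSpec(), grid)["PTV"]
        count = ptv.indices(grid).size
        analytic = 4.0 / 3.0 * math.pi * 15.0**3  # 1 mm^3 voxels
        assert abs(count - analytic) / analytic < 0.02

    def test_grid_too_small_raises_with_extent(self):
        tiny = GridSpec.centered(half_extent=10.0, spacing=2.0)
        with pytest.raises(ValueError, match="grid too small"):
            make_phantom(PhantomSpec(), tiny)

    def test_anisotropic_ptv_margin_rejected(self):
        with pytest.raises(ValueError, match="anisotropic"):
            PhantomSpec(ptv_margin=(5.0, 5.0, 7.0))

    @pytest.mark.parametrize("field,value", [
        ("gtv_radius", 0.0), ("ctv_margin", -1.0), ("tumor_density", 2.5),
        ("lung_density", 0.0),
    ])
    def test_invalid_phantom_fields(self, field, value):
        with pytest.raises(ValueError):
            PhantomSpec(**{field: value})


class TestDoseGeneration:
    def test_point_style_center_voxel_equals_prescription(self, point_dose):
        center = tuple(n // 2 for n in point_dose.grid.shape)
        assert point_dose.values[center] == pytest.approx(48.0, abs=1e-12)

    @pytest.mark.parametrize("idl,expected_max", [(60.0, 80.0), (70.0, 480.0 / 7.0), (80.0, 60.0)])
    def test_marginal_max_dose_is_prescription_over_id(
        self, structures, grid, idl, expected_max
    ):
        dose = generate_dose(
            DoseProfileParams("marginal", isodose_level=idl), structures, grid, 48.0
        )
        assert dose.values.max() == pytest.approx(expected_max, rel=1e-9)

    @pytest.mark.parametrize("idl", [60.0, 70.0, 80.0])
    def test_marginal_ptv_d95_equals_prescription(self, structures, grid, idl):
        dose = generate_dose(
            DoseProfileParams("marginal", isodose_level=idl), structures, grid, 48.0
        )
        assert dvh_quantile(dose, structures["PTV"], 0.95) == pytest.approx(48.0, rel=1e-9)

    @pytest.mark.parametrize("style,idl", [("point", None), ("marginal", 60.0), ("marginal", 80.0)])
    def test_radial_monotonicity_every_voxel(self, structures, grid, style, idl):
        dose = generate_dose(DoseProfileParams(style, idl), structures, grid, 48.0)
        rho = grid.radial_distance((0.0, 0.0, 0.0)).ravel()
        order = np.argsort(rho, kind="stable")
        v = dose.values.ravel()[order]
        assert np.all(np.diff(v) <= 1e-9)

    def test_monotone_on_random_radius_pairs(self, point_dose, grid):
        rng = np.random.default_rng(0)
        rho = grid.radial_distance((0.0, 0.0, 0.0)).ravel()
        v = point_dose.values.ravel()
        i = rng.integers(0, rho.size, size=10_000)
        j = rng.integers(0, rho.size, size=10_000)
        lo, hi = np.where(rho[i] < rho[j], i, j), np.where(rho[i] < rho[j], j, i)
        assert np.all(v[lo] >= v[hi] - 1e-9)

    def test_mirror_symmetry(self, marginal80_dose):
        v = marginal80_dose.values
        np.testing.assert_allclose(v, np.flip(v), rtol=0, atol=1e-9)

    def test_larger_id_has_steeper_relative_falloff_outside_prescription(
        self, structures, grid
    ):
        """Relative dose beyond the prescription surface is ordered 60>=70>=80,
        so a larger isodose level cannot yield a larger downstream margin."""
        r95 = coverage_radius(structures["PTV"], grid)
        profiles = {}
        for idl in (60.0, 70.0, 80.0):
            dose = generate_dose(
                DoseProfileParams("marginal", isodose_level=idl), structures, grid, 48.0
            )
            rho = grid.radial_distance((0.0, 0.0, 0.0)).ravel()
            v = dose.values.ravel() / 48.0  # relative to prescription
            sel = (rho >= r95) & (rho <= r95 + 20.0)
            order = np.argsort(rho[sel])
            profiles[idl] = v[sel][order]
        assert np.all(profiles[60.0] >= profiles[70.0] - 1e-9)
        assert np.all(profiles[70.0] >= profiles[80.0] - 1e-9)

    def test_unattainably_wide_penumbra_raises(self, structures, grid):
        params = DoseProfileParams("marginal", isodose_level=80.0, penumbra_width=300.0)
        with pytest.raises(NormalizationError):
            generate_dose(params, structures, grid, 48.0)

    def test_marginal_requires_isodose_level(self):
        with pytest.raises(ValueError):
            DoseProfileParams("marginal")

    def test_isodose_level_bounds(self):
        with pytest.raises(ValueError):
            DoseProfileParams("marginal", isodose_level=50.0)


class TestDensityPenumbra:
    def test_reference_density_maps_to_default_width(self):
        assert density_to_penumbra(1.0) == pytest.approx(4.0)
        assert density_to_penumbra(0.4) == pytest.approx(8.0)

    def test_strictly_decreasing_and_positive(self):
        densities = np.linspace(0.05, 2.0, 50)
        widths = np.array([density_to_penumbra(d) for d in densities])
        assert np.all(widths > 0)
        assert np.all(np.diff(widths) < 0)

    def test_study_sweep_gives_three_distinct_widths(self):
        w = [density_to_penumbra(d) for d in (0.4, 0.7, 1.0)]
        assert w[0] > w[1] > w[2] > 0

    def test_nonpositive_density_rejected(self):
        with pytest.raises(ValueError):
            density_to_penumbra(0.0)


class TestGridIO:
    def test_nrrd_round_trip(self, marginal80_dose, tmp_path):
        path = tmp_path / "dose.nrrd"
        write_dose_grid(marginal80_dose, path)
        back = read_dose_grid(path)
        assert back.quantity == "physical"
        assert back.grid == marginal80_dose.grid
        np.testing.assert_allclose(back.values, marginal80_dose.values, rtol=1e-6)

    def test_raw_fallback_round_trip_is_bit_exact(self, point_dose, tmp_path):
        path = tmp_path / "dose.json"
        write_dose_grid(point_dose, path)
        back = read_dose_grid(path)
        assert back.grid == point_dose.grid
        np.testing.assert_array_equal(
            back.values, point_dose.values.astype("<f4").astype(float)
        )

    def test_structure_mask_export(self, structures, grid, tmp_path):
        from dosimargin import write_structure_mask

        path = tmp_path / "ptv.nrrd"
        write_structure_mask(structures["PTV"], grid, path)
        back = read_dose_grid(path)
        np.testing.assert_array_equal(
            back.values.astype(bool), structures["PTV"].mask(grid)
        )
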