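"""Digital phantoms, CT simulation and the synthetic cohort."""

import numpy as np
import pytest

from lungtcm import (
    CavityPhantomSpec,
    CTSimConfig,
    FoamSpec,
    build_cavity_phantom,
    build_foam_phantom,
    compute_ravh,
    fractional_mass,
    generate_cohort,
    simulate_ct,
)
from lungtcm.phantoms import simulate_ct_multi
from lungtcm.ravh import DAMAGED_LUNG_BIN

FAST_FOAM = FoamSpec(ppi=10, total_mass_g=2.82)


class TestCavityPhantom:
    def test_single_cavity_cube_air_volume(self):
        # one cavity spanning the full 20x20x20 mm interior holds 8 cm^3
        spec = CavityPhantomSpec(septum_width=1.0, cavity_width=20.0, n_cavities=1)
        scene = build_cavity_phantom(spec, 0.25)
        assert scene.ground_truth["air_volume_cm3"] == pytest.approx(8.0, rel=1e-6)

    def test_grid_count_matches_analytic_geometry(self):
        spec = CavityPhantomSpec(septum_width=1.0, cavity_width=4.0, n_cavities=4)
        scene = build_cavity_phantom(spec, 0.1)
        assert scene.ground_truth["air_volume_cm3"] == pytest.approx(
            spec.analytic_air_volume_cm3, rel=1e-6
        )
        # solid + air partition the outer box exactly
        ox, oy, oz = spec.derived_outer_dims
        total = scene.ground_truth["air_volume_cm3"] + scene.ground_truth["solid_volume_cm3"]
        assert total == pytest.approx(ox * oy * oz / 1000.0, rel=1e-9)

    def test_unresolvable_septum_raises(self):
        spec = CavityPhantomSpec(septum_width=0.7, cavity_width=2.8, n_cavities=8)
        with pytest.raises(ValueError):
            build_cavity_phantom(spec, 0.5)  # < 4 samples across 0.7 mm
        with pytest.raises(ValueError):
            build_cavity_phantom(spec, 0.0)

    def test_explicit_outer_dims_overflow_raises(self):
        with pytest.raises(ValueError):
            CavityPhantomSpec(
                septum_width=0.7, cavity_width=2.8, n_cavities=8,
                outer_dims=(30.0, 30.0, 30.0),  # inner width 20 < 27.3 needed
            )


class TestFoamPhantom:
    def test_target_fraction_from_printed_mass(self):
        # 2.82 g / (1.12 g/cm^3 x 125 cm^3) = 2.014%
        assert FAST_FOAM.target_fraction == pytest.approx(0.02014, abs=2e-5)

    def test_realized_fraction_matches_target(self):
        scene = build_foam_phantom(FAST_FOAM, 0.05, (10.0, 10.0, 5.0))
        realized = scene.material_map.mean()
        assert realized == pytest.approx(FAST_FOAM.target_fraction, rel=0.01)

    def test_ground_truth_mass_scales_with_region(self):
        small = build_foam_phantom(FAST_FOAM, 0.05, (10.0, 10.0, 5.0))
        # the slab holds (10*10*5)/50^3 of the cube volume, so about that
        # share of the total mass (uniform pores)
        share = (10 * 10 * 5) / 50.0 ** 3
        assert small.ground_truth["solid_mass_g"] == pytest.approx(
            FAST_FOAM.total_mass_g * share, rel=0.01
        )

    def test_unresolved_strut_radius_raises(self):
        with pytest.raises(ValueError):
            build_foam_phantom(FAST_FOAM, 0.5, (10.0, 10.0, 5.0))

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            FoamSpec(ppi=10, total_mass_g=20.0)  # fraction > 10%
        with pytest.raises(ValueError):
            FoamSpec(ppi=0, total_mass_g=1.0)


class TestSimulateCT:
    def scene_of(self, occupancy, resolution=0.5):
        occupancy = np.asarray(occupancy, dtype=bool)
        vox = resolution ** 3 / 1000.0
        gt = {
            "solid_volume_cm3": float(occupancy.sum()) * vox,
            "air_volume_cm3": float((~occupancy).sum()) * vox,
        }
        from lungtcm.phantoms import PhantomScene

        return PhantomScene(occupancy, resolution, gt)

    def test_pure_materials_map_to_calibration_values(self):
        cfg = CTSimConfig(recon_spacing_mm=(1.0, 1.0, 1.0))
        solid = simulate_ct(self.scene_of(np.ones((8, 8, 8))), cfg)
        air = simulate_ct(self.scene_of(np.zeros((8, 8, 8))), cfg)
        assert solid.values == pytest.approx(113.4)
        assert air.values == pytest.approx(-999.5, abs=1e-3)

    def test_blur_conserves_interior_mean(self, rng):
        occ = rng.random((24, 24, 24)) < 0.3
        scene = self.scene_of(occ, resolution=0.5)
        sharp = simulate_ct(scene, CTSimConfig(psf_fwhm_mm=0.0, recon_spacing_mm=(1, 1, 1), boundary="wrap"))
        blurred = simulate_ct(scene, CTSimConfig(psf_fwhm_mm=2.0, recon_spacing_mm=(1, 1, 1), boundary="wrap"))
        assert blurred.values.mean() == pytest.approx(sharp.values.mean(), rel=1e-6)

    def test_recon_finer_than_scene_raises(self):
        scene = self.scene_of(np.ones((4, 4, 4)), resolution=0.5)
        with pytest.raises(ValueError):
            simulate_ct(scene, CTSimConfig(recon_spacing_mm=(0.1, 0.1, 0.1)))

    def test_noise_is_seed_reproducible(self):
        scene = self.scene_of(np.zeros((8, 8, 8)))
        cfg = CTSimConfig(recon_spacing_mm=(1, 1, 1), noise_sd_hu=20.0, seed=42)
        a = simulate_ct(scene, cfg)
        b = simulate_ct(scene, cfg)
        np.testing.assert_array_equal(a.values, b.values)
        c = simulate_ct(scene, CTSimConfig(recon_spacing_mm=(1, 1, 1), noise_sd_hu=20.0, seed=43))
        assert not np.array_equal(a.values, c.values)

    def test_multi_thickness_consistent_with_single(self):
        scene = self.scene_of(np.arange(1000).reshape(10, 10, 10) % 3 == 0, resolution=0.5)
        multi = simulate_ct_multi(scene, CTSimConfig(recon_spacing_mm=(1, 1, 1)), (1.0, 2.5))
        single = simulate_ct(scene, CTSimConfig(recon_spacing_mm=(1.0, 1.0, 1.0)))
        np.testing.assert_array_equal(multi[1.0].values, single.values)
        assert multi[2.5].shape[0] < multi[1.0].shape[0]


class TestFractionalMass:
    def test_printed_example(self):
        assert fractional_mass(FAST_FOAM, 4.7) == pytest.approx(0.26508)

    def test_full_side_and_limits(self):
        assert fractional_mass(FAST_FOAM, 50.0) == pytest.approx(FAST_FOAM.total_mass_g)
        assert fractional_mass(FAST_FOAM, 1e-6) == pytest.approx(0.0, abs=1e-6)
        with pytest.raises(ValueError):
            fractional_mass(FAST_FOAM, 0.0)
        with pytest.raises(ValueError):
            fractional_mass(FAST_FOAM, 60.0)


class TestGenerateCohort:
    def test_same_seed_is_bit_reproducible(self):
        a = generate_cohort(2, 2, seed=5)
        b = generate_cohort(2, 2, seed=5)
        for (fa, ma, la), (fb, mb, lb) in zip(a, b):
            np.testing.assert_array_equal(fa.values, fb.values)
            assert la == lb

    def test_control_group_mode_at_normal_lung_peak(self):
        from lungtcm import group_mean_ravh

        cohort = generate_cohort(10, 1, seed=3, n_voxels=20000)
        ravhs = [compute_ravh(f, m) for f, m, lab in cohort if lab == "control"]
        mean_ravh = group_mean_ravh(ravhs)
        # between-subject spread averages out: the group mode sits on the
        # 88.75%-centred bin (index 35)
        assert int(np.argmax(mean_ravh.relative_volumes)) == 35

    def test_trapped_air_fraction_recovered(self):
        fmap, mask, label = generate_cohort(
            1, 1, seed=9, n_voxels=100_000, trapped_air_fraction=0.30
        )[1]
        assert label == "copd"
        ravh = compute_ravh(fmap, mask)
        rv_dl = ravh.rv(DAMAGED_LUNG_BIN)
        # binomial sampling error at n=1e5 is ~0.14 percentage points (1 sd)
        assert rv_dl == pytest.approx(30.0, abs=1.0)

    def test_validation(self):
        with pytest.raises(ValueError):
            generate_cohort(0, 1, seed=1)
        with pytest.raises(ValueError):
            generate_cohort(1, 1, seed=1, trapped_air_fraction=1.5)
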