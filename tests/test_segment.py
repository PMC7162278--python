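"""Threshold/Otsu segmentation, lung masking and airway removal."""

import numpy as np
import pytest

from lungtcm import (
    AirwaySeed,
    FractionMap,
    HUVolume,
    lung_mask,
    otsu_threshold,
    percent_emphysema,
    remove_airways,
    threshold_segment,
)
from lungtcm.segment import BinaryMask


from _oracles import brute_force_otsu


class TestThresholdSegment:
    def test_constant_volumes(self, constant_volume):
        assert threshold_segment(constant_volume(-1000), -850, "below").values.all()
        assert not threshold_segment(constant_volume(0), -850, "below").values.any()

    def test_below_above_partition(self, rng):
        vol = HUVolume(rng.choice([-1000.0, 100.0], (6, 6, 6)), (1, 1, 1))
        below = threshold_segment(vol, -850, "below").values
        above = threshold_segment(vol, -850, "above").values
        assert np.all(below ^ above)  # no voxel equals the threshold here

    def test_volume_monotone_in_threshold(self, rng):
        vol = HUVolume(rng.uniform(-1000, 0, (8, 8, 8)), (1, 1, 1))
        volumes = [threshold_segment(vol, t, "below").volume_cm3() for t in (-950, -900, -850, -500)]
        assert volumes == sorted(volumes)


class TestOtsu:
    def test_bimodal_split_at_midpoint(self):
        values = np.array([-1000.0] * 50 + [0.0] * 50).reshape(2, 5, 10)
        t = otsu_threshold(HUVolume(values, (1, 1, 1)))
        assert abs(t - (-500.0)) <= 1.0

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(20):
            hu = rng.integers(-1000, 200, size=rng.integers(10, 200))
            if np.unique(hu).size < 2:
                continue
            vol = HUVolume(hu.astype(float).reshape(1, 1, -1), (1, 1, 1))
            assert otsu_threshold(vol) == pytest.approx(brute_force_otsu(hu))

    def test_constant_region_raises(self, constant_volume):
        with pytest.raises(ValueError):
            otsu_threshold(constant_volume(-500.0))

    def test_mask_restricts_histogram(self, rng):
        hu = np.full((4, 4, 4), 500.0)
        hu[0] = -1000.0
        hu[1] = 0.0
        vol = HUVolume(hu, (1, 1, 1))
        mask = np.zeros((4, 4, 4), dtype=bool)
        mask[:2] = True  # exclude the 500 HU region entirely
        assert abs(otsu_threshold(vol, mask) - (-500.0)) <= 1.0


def chest_like_scene():
    """Air background, zero-fraction body, two lung ellipsoids, one speck."""
    f = np.ones((24, 30, 30))  # exterior air
    f[2:22, 3:27, 3:27] = 0.0  # body
    z, y, x = np.ogrid[:24, :30, :30]
    left = ((z - 12) / 8.0) ** 2 + ((y - 15) / 9.0) ** 2 + ((x - 9) / 4.0) ** 2 <= 1
    right = ((z - 12) / 8.0) ** 2 + ((y - 15) / 9.0) ** 2 + ((x - 21) / 4.0) ** 2 <= 1
    f[left] = 0.9
    f[right] = 0.9
    f[5, 5, 14] = 0.5  # isolated speck, smaller than either lung
    return FractionMap(f, (1.0, 1.0, 1.0)), left, right


class TestLungMask:
    def test_two_lungs_kept_body_and_speck_excluded(self):
        fmap, left, right = chest_like_scene()
        mask = lung_mask(fmap)
        np.testing.assert_array_equal(mask.values, left | right)

    def test_single_ellipsoid(self):
        f = np.ones((20, 20, 20))
        f[2:18, 2:18, 2:18] = 0.0
        z, y, x = np.ogrid[:20, :20, :20]
        ell = ((z - 10) / 5.0) ** 2 + ((y - 10) / 6.0) ** 2 + ((x - 10) / 4.0) ** 2 <= 1
        f[ell] = 0.9
        fmap = FractionMap(f, (1, 1, 1))
        mask = lung_mask(fmap, keep_components=1)
        np.testing.assert_array_equal(mask.values, ell)

    def test_no_candidate_raises(self):
        f = np.ones((6, 6, 6))  # everything is boundary-connected exterior air
        with pytest.raises(ValueError):
            lung_mask(FractionMap(f, (1, 1, 1)))


class TestRemoveAirways:
    def make_lung_with_tube(self):
        f = np.zeros((20, 12, 12))
        lung = np.zeros_like(f, dtype=bool)
        lung[4:16, 2:10, 2:10] = True
        f[lung] = 0.90
        f[0:10, 5:7, 5:7] = 1.0  # trachea entering the lung from the top
        return FractionMap(f, (1, 1, 1)), BinaryMask(lung | (f == 1.0), (1, 1, 1), "lung")

    def test_tube_removed_lung_intact(self):
        fmap, lungs = self.make_lung_with_tube()
        cleaned = remove_airways(fmap, lungs, AirwaySeed((0, 5, 5)))
        assert not cleaned.values[fmap.values == 1.0].any()
        assert cleaned.values[(fmap.values == 0.90)].all()

    def test_output_subset_of_input(self):
        fmap, lungs = self.make_lung_with_tube()
        cleaned = remove_airways(fmap, lungs, AirwaySeed((0, 5, 5)))
        assert not (cleaned.values & ~lungs.values).any()

    def test_seed_below_criterion_raises(self):
        fmap, lungs = self.make_lung_with_tube()
        with pytest.raises(ValueError):
            remove_airways(fmap, lungs, AirwaySeed((10, 3, 3), 0.95))  # a 0.90 voxel

    def test_connected_high_fraction_blob_also_removed(self):
        # documented consequence: a 0.99-fraction blob touching the airway
        # column is grown into and removed (flood-fill oracle by construction)
        fmap, lungs = self.make_lung_with_tube()
        fmap.values[10:12, 5:7, 5:7] = 0.99  # continues the tube inside the lung
        cleaned = remove_airways(fmap, lungs, AirwaySeed((0, 5, 5)))
        assert not cleaned.values[10:12, 5:7, 5:7].any()


class TestFindTracheaSeed:
    def test_finds_round_tube_not_elongated_fissure(self):
        from lungtcm import find_trachea_seed

        f = np.zeros((12, 30, 30))
        f[0:12, 14:17, 14:17] = 1.0   # round trachea column
        f[0:12, 5:6, 4:26] = 1.0      # elongated air-filled fissure artifact
        seed = find_trachea_seed(FractionMap(f, (1, 1, 1)))
        z, y, x = seed.position
        assert 14 <= y < 17 and 14 <= x < 17
        assert f[z, y, x] == 1.0

    def test_border_touching_air_ignored(self):
        from lungtcm import find_trachea_seed

        f = np.zeros((6, 10, 10))
        f[:, 0:3, :] = 1.0  # exterior air touching the slice border
        with pytest.raises(ValueError):
            find_trachea_seed(FractionMap(f, (1, 1, 1)))


class TestPercentEmphysema:
    @pytest.mark.parametrize(
        "fill, threshold, expected",
        [(-980.0, -950.0, 100.0), (-800.0, -950.0, 0.0)],
    )
    def test_uniform_lung(self, constant_volume, fill, threshold, expected):
        vol = constant_volume(fill, shape=(4, 4, 4))
        mask = BinaryMask(np.ones((4, 4, 4), dtype=bool), (1, 1, 1), "lung")
        assert percent_emphysema(vol, mask, threshold) == expected

    def test_half_and_half(self):
        values = np.full((2, 4, 4), -980.0)
        values[1] = -800.0
        vol = HUVolume(values, (1, 1, 1))
        mask = BinaryMask(np.ones_like(values, dtype=bool), (1, 1, 1), "lung")
        assert percent_emphysema(vol, mask, -910.0) == 50.0

    def test_monotone_in_threshold(self, rng):
        vol = HUVolume(rng.uniform(-1000, -700, (6, 6, 6)), (1, 1, 1))
        mask = BinaryMask(np.ones((6, 6, 6), dtype=bool), (1, 1, 1), "lung")
        pes = [percent_emphysema(vol, mask, t) for t in (-950, -910, -850)]
        assert pes == sorted(pes)

    def test_empty_mask_raises(self, constant_volume):
        mask = BinaryMask(np.zeros((4, 5, 6), dtype=bool), (1, 1, 1), "lung")
        with pytest.raises(ValueError):
            percent_emphysema(constant_volume(-900.0), mask, -910.0)
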