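"""Spot-meter and region-area echotexture quantification."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from testecho import synthetic as syn
from testecho.echotexture import (
    SpotPlacementError,
    UltrasoundFrame,
    categorize_echogenicity,
    measure_frame,
    percent_echogenicity,
    place_spots,
    region_area_stats,
    spot_meter_stats,
    spot_side_pixels,
    structure_gi,
)

from conftest import make_flat_frame


class TestPlaceSpots:
    def test_full_square_mask_yields_nine_disjoint_14px_spots(self):
        # 2 mm^2 spot at 0.1 mm/px -> sqrt(2)/0.1 = 14.1 -> 14 px side
        frame = make_flat_frame(value=100, size=300, mm_per_pixel=0.1)
        spots = place_spots(frame)
        assert len(spots) == 9
        assert all(side == 14 for _, _, side in spots)
        cover = np.zeros((300, 300), dtype=int)
        for r, c, side in spots:
            cover[r:r + side, c:c + side] += 1
        assert cover.max() == 1  # non-overlapping

    def test_tiny_mask_is_infeasible(self):
        masks = {"parenchyma": np.zeros((60, 60), dtype=bool)}
        masks["parenchyma"][10:12, 10:12] = True
        frame = make_flat_frame(size=60, masks=masks)
        with pytest.raises(SpotPlacementError, match="infeasible"):
            place_spots(frame)

    def test_spots_avoid_mediastinum_band(self):
        par = np.ones((300, 300), dtype=bool)
        mt = np.zeros_like(par)
        mt[140:160, :] = True
        frame = make_flat_frame(size=300, mm_per_pixel=0.1,
                                masks={"parenchyma": par, "mediastinum": mt})
        for r, c, side in place_spots(frame):
            assert not mt[r:r + side, c:c + side].any()
            assert par[r:r + side, c:c + side].all()

    def test_spot_side_rounding(self):
        assert spot_side_pixels(0.1) == 14
        assert spot_side_pixels(0.15) == 9


class TestSpotMeterStats:
    def test_uniform_image(self):
        frame = make_flat_frame(value=100, size=300, mm_per_pixel=0.1)
        mean, het = spot_meter_stats(frame, place_spots(frame))
        assert mean == 100 and het == 0

    def test_closed_form_on_nine_spot_means(self):
        # eight spots at 90, one at 108: mean 92, SD (n-1) = 6
        pixels = np.full((100, 100), 90, dtype=np.uint8)
        pixels[:10, 90:] = 108
        frame = UltrasoundFrame(pixels=pixels, mm_per_pixel=1.0,
                                masks={"parenchyma": np.ones_like(pixels, bool)})
        spots = [(r, c, 5) for r in (10, 40, 70) for c in (10, 40, 70)]
        spots[-1] = (0, 95, 5)
        mean, het = spot_meter_stats(frame, spots)
        assert mean == pytest.approx(92)
        assert het == pytest.approx(6)

    def test_requires_two_spots(self):
        frame = make_flat_frame()
        with pytest.raises(ValueError):
            spot_meter_stats(frame, [(0, 0, 5)])


class TestRegionAreaStats:
    def test_uniform_image(self):
        mean, sd = region_area_stats(make_flat_frame(value=100))
        assert (mean, sd) == (100.0, 0.0)

    def test_two_point_distribution(self):
        pixels = np.zeros((40, 40), dtype=np.uint8)
        pixels[:, 20:] = 255
        frame = UltrasoundFrame(pixels=pixels, mm_per_pixel=0.1,
                                masks={"parenchyma": np.ones_like(pixels, bool)})
        mean, sd = region_area_stats(frame)
        n = pixels.size
        assert mean == pytest.approx(127.5)
        assert sd == pytest.approx(127.5 * np.sqrt(n / (n - 1)))

    def test_mediastinum_band_is_excluded(self):
        base = make_flat_frame(value=100, size=80)
        pixels = base.pixels.copy()
        mt = np.zeros((80, 80), dtype=bool)
        mt[38:42, :] = True
        pixels[mt] = 250  # bright band inside the outlined parenchyma
        with_band = UltrasoundFrame(
            pixels=pixels, mm_per_pixel=0.1,
            masks={"parenchyma": base.masks["parenchyma"], "mediastinum": mt})
        assert region_area_stats(with_band) == region_area_stats(base)

    def test_matches_bruteforce_accumulation_on_small_frames(self):
        rng = np.random.default_rng(42)
        for _ in range(5):
            pixels = rng.integers(0, 256, (48, 48)).astype(np.uint8)
            par = rng.random((48, 48)) < 0.6
            mt = rng.random((48, 48)) < 0.1
            par[0, 0] = True
            frame = UltrasoundFrame(pixels=pixels, mm_per_pixel=0.1,
                                    masks={"parenchyma": par, "mediastinum": mt})
            vals = [float(pixels[i, j]) for i in range(48) for j in range(48)
                    if par[i, j] and not mt[i, j]]
            mean, sd = region_area_stats(frame)
            assert mean == pytest.approx(np.mean(vals))
            assert sd == pytest.approx(np.std(vals, ddof=1))

    @given(shift=st.integers(min_value=-30, max_value=30))
    def test_constant_shift_moves_mean_not_sd(self, shift):
        rng = np.random.default_rng(7)
        base = rng.integers(60, 160, (32, 32)).astype(int)
        masks = {"parenchyma": np.ones((32, 32), dtype=bool)}
        f0 = UltrasoundFrame(pixels=base.astype(np.uint8),
                             mm_per_pixel=0.1, masks=masks)
        f1 = UltrasoundFrame(pixels=(base + shift).astype(np.uint8),
                             mm_per_pixel=0.1, masks=masks)
        m0, s0 = region_area_stats(f0)
        m1, s1 = region_area_stats(f1)
        assert m1 - m0 == pytest.approx(shift)
        assert s1 == pytest.approx(s0)


class TestStructureGI:
    def test_capsule_rim_zero_noise(self):
        profile = syn.MaturationProfile(het_start=0, het_end=0, noise_sd=0)
        frame = syn.render_bmode_frame(profile, 36, seed=1)
        assert structure_gi(frame, "capsule") == pytest.approx(
            profile.gi_capsule(36), abs=0.51)  # 8-bit quantization

    def test_preonset_mediastinum_is_not_imaged(self, default_profile):
        frame = syn.render_bmode_frame(default_profile, 4, seed=1)
        assert structure_gi(frame, "mediastinum") is None

    def test_rendered_mediastinum_recovers_trajectory(self, default_profile):
        frame = syn.render_bmode_frame(default_profile, 36, seed=5)
        target = default_profile.gi_mediastinum(36)
        n = frame.masks["mediastinum"].sum()
        se = 6.0 / np.sqrt(n)
        assert structure_gi(frame, "mediastinum") == pytest.approx(
            target, abs=3 * se + 0.5)

    def test_unknown_structure_rejected(self, default_profile):
        frame = syn.render_bmode_frame(default_profile, 20, seed=1)
        with pytest.raises(ValueError):
            structure_gi(frame, "epididymis")


class TestRatiosAndCategories:
    def test_percent_echogenicity_arithmetic(self):
        assert percent_echogenicity(215, 115) == pytest.approx(186.96, abs=0.01)
        assert percent_echogenicity(123.4, 123.4) == 100
        with pytest.raises(ZeroDivisionError):
            percent_echogenicity(190, 0)

    @pytest.mark.parametrize("gi,expected", [
        (0, "low"), (85, "low"), (85.4, "low"),
        (85.5, "moderate"), (86, "moderate"), (170, "moderate"),
        (171, "high"), (255, "high"),
    ])
    def test_category_boundaries(self, gi, expected):
        assert categorize_echogenicity(gi) == expected

    def test_category_out_of_range(self):
        for bad in (-1, 256):
            with pytest.raises(ValueError):
                categorize_echogenicity(bad)

    @given(a=st.floats(min_value=0, max_value=255),
           b=st.floats(min_value=0, max_value=255))
    def test_category_is_total_and_monotone(self, a, b):
        order = {"low": 0, "moderate": 1, "high": 2}
        ca, cb = categorize_echogenicity(a), categorize_echogenicity(b)
        if a <= b:
            assert order[ca] <= order[cb]


class TestTechniqueAgreement:
    def test_spot_and_region_means_agree_on_homogeneous_speckle(
            self, default_profile):
        """The two ROI conventions measure the same parenchyma."""
        close = 0
        for seed in range(100):
            frame = syn.render_bmode_frame(default_profile, 30, seed=seed)
            res = measure_frame(frame)
            assert res.gi_parenchyma_spot is not None
            if abs(res.gi_parenchyma_spot - res.gi_parenchyma_region) < 2:
                close += 1
        assert close >= 95

    def test_zero_noise_plateau_mean_is_exact(self):
        profile = syn.MaturationProfile(gi_slope=2.5, gi_plateau_drift=0,
                                        het_start=0, het_end=0, noise_sd=0)
        frame = syn.render_bmode_frame(profile, 34, seed=1)
        # plateau GI = 55 + 2.5 * 24 = 115, exactly representable in 8 bits
        assert profile.gi_parenchyma(34) == 115
        res = measure_frame(frame)
        assert res.gi_parenchyma_spot == 115
        assert res.gi_parenchyma_region == 115
        assert res.het_spot == 0 and res.het_region == 0
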