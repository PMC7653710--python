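"""Plaque detection, burden, band geometry and band quantification."""

import numpy as np
import pytest
from scipy import ndimage as ndi

from plaqueband.plaques import (
    band_mask,
    count_plaque_microglia,
    detect_plaques,
    detect_somata,
    diameter_neurite_relation,
    plaque_burden,
    quantify_band,
)


def rasterized_disk(shape, cy, cx, radius):
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    return np.hypot(yy - cy, xx - cx) <= radius


class TestDetectPlaques:
    def test_empty_mask(self):
        assert detect_plaques(np.zeros((20, 20), bool), 1.0) == []

    def test_disk_radius_10px_equivalent_diameter(self):
        """Disk of radius 10 px at 1 um/px: d = 2*sqrt(A/pi) within 5% of 20 um."""
        mask = rasterized_disk((64, 64), 32, 32, 10)
        plaques = detect_plaques(mask, 1.0)
        assert len(plaques) == 1
        d_expected = 2 * np.sqrt(mask.sum() / np.pi)
        assert plaques[0].equivalent_diameter_um == pytest.approx(d_expected, rel=1e-9)
        assert abs(plaques[0].equivalent_diameter_um - 20.0) / 20.0 < 0.05

    def test_8um_disk_filtered_by_minimum_diameter_rule(self):
        mask = rasterized_disk((64, 64), 32, 32, 4)  # 8 um diameter at 1 um/px
        assert detect_plaques(mask, 1.0) == []

    def test_20um_disk_retained(self):
        mask = rasterized_disk((64, 64), 32, 32, 10)
        assert len(detect_plaques(mask, 1.0)) == 1

    def test_translation_invariance(self):
        base = rasterized_disk((100, 100), 30, 30, 8)
        shifted = np.roll(np.roll(base, 15, axis=0), 20, axis=1)
        p0 = detect_plaques(base, 1.0)[0]
        p1 = detect_plaques(shifted, 1.0)[0]
        assert p1.equivalent_diameter_um == p0.equivalent_diameter_um
        assert p1.centroid_um[0] == pytest.approx(p0.centroid_um[0] + 15)
        assert p1.centroid_um[1] == pytest.approx(p0.centroid_um[1] + 20)

    def test_deterministic_row_major_ordering(self):
        mask = np.zeros((80, 80), bool)
        mask |= rasterized_disk(mask.shape, 60, 20, 8)
        mask |= rasterized_disk(mask.shape, 20, 60, 8)
        plaques = detect_plaques(mask, 1.0)
        assert plaques[0].centroid_um[0] < plaques[1].centroid_um[0]
        assert [p.id for p in plaques] == [0, 1]

    def test_border_component_flagged_clipped(self):
        mask = rasterized_disk((40, 40), 0, 20, 8)
        p = detect_plaques(mask, 1.0)[0]
        assert p.border_clipped


class TestBurden:
    def test_full_coverage_is_100_percent(self):
        roi = np.ones((10, 10), bool)
        assert plaque_burden(roi, roi, 1.0).burden_percent == 100.0

    def test_empty_plaque_mask_is_zero(self):
        roi = np.ones((10, 10), bool)
        assert plaque_burden(np.zeros_like(roi), roi, 1.0).burden_percent == 0.0

    def test_empty_roi_rejected(self):
        with pytest.raises(ValueError, match="ROI"):
            plaque_burden(np.ones((5, 5), bool), np.zeros((5, 5), bool), 1.0)

    def test_matches_pixel_counting_oracle(self, rng):
        """Random masks: burden equals explicit loop counting."""
        for _ in range(200):
            pm = rng.uniform(size=(12, 12)) < 0.3
            roi = rng.uniform(size=(12, 12)) < 0.7
            if not roi.any():
                continue
            inter = sum(
                1 for y in range(12) for x in range(12) if pm[y, x] and roi[y, x]
            )
            expect = 100.0 * inter / roi.sum()
            assert plaque_burden(pm, roi, 2.0).burden_percent == pytest.approx(expect)


class TestBandMask:
    def test_width_zero_empty(self):
        mask = rasterized_disk((60, 60), 30, 30, 8)
        p = detect_plaques(mask, 1.0)[0]
        band = band_mask(p, 0.0, mask.shape, 1.0)
        assert not band.mask.any()

    def test_annulus_area_matches_analytic_value(self):
        """r=20 um disk, 30 um band at 0.5 um/px: area within 3% of
        pi*(50^2 - 20^2)."""
        px = 0.5
        shape = (240, 240)
        mask = rasterized_disk(shape, 120, 120, 20 / px)
        p = detect_plaques(mask, px)[0]
        band = band_mask(p, 30.0, shape, px)
        assert not band.clipped
        analytic = np.pi * (50.0**2 - 20.0**2)
        assert abs(band.area_um2 - analytic) / analytic < 0.03

    def test_band_excludes_plaque_interior(self):
        mask = rasterized_disk((80, 80), 40, 40, 10)
        p = detect_plaques(mask, 1.0)[0]
        band = band_mask(p, 10.0, mask.shape, 1.0)
        assert not (band.full_mask() & mask).any()

    def test_overlapping_bands_are_independent(self):
        mask = np.zeros((100, 160), bool)
        mask |= rasterized_disk(mask.shape, 50, 50, 10)
        mask |= rasterized_disk(mask.shape, 50, 100, 10)
        p0, p1 = detect_plaques(mask, 1.0)
        b0 = band_mask(p0, 30.0, mask.shape, 1.0)
        b1 = band_mask(p1, 30.0, mask.shape, 1.0)
        shared = b0.full_mask() & b1.full_mask()
        assert shared.any()  # a pixel may belong to both bands

    def test_clipped_flag_at_border(self):
        mask = rasterized_disk((60, 60), 10, 30, 8)
        p = detect_plaques(mask, 1.0)[0]
        band = band_mask(p, 30.0, mask.shape, 1.0)
        assert band.clipped


class TestQuantifyBand:
    def make(self):
        shape = (120, 120)
        mask = rasterized_disk(shape, 60, 60, 10)
        p = detect_plaques(mask, 1.0)[0]
        band = band_mask(p, 30.0, shape, 1.0)
        return shape, p, band

    def test_empty_marker_mask(self):
        shape, p, band = self.make()
        q = quantify_band(np.zeros(shape), np.zeros(shape, bool), p, band)
        assert q.positive_area_inside_um2 == 0
        assert q.positive_area_band_um2 == 0
        assert q.object_count_band == 0

    def test_marker_saturating_the_band(self):
        shape, p, band = self.make()
        marker = band.full_mask()
        q = quantify_band(marker.astype(float), marker, p, band)
        assert q.positive_area_band_um2 == pytest.approx(band.area_um2)
        assert q.object_count_band == 1

    def test_mean_intensity_over_all_band_pixels(self):
        shape, p, band = self.make()
        img = np.full(shape, 7.0)
        q = quantify_band(img, np.zeros(shape, bool), p, band)
        assert q.mean_intensity_band == pytest.approx(7.0)

    def test_area_conservation(self, rng):
        shape, p, band = self.make()
        marker = rng.uniform(size=shape) < 0.4
        q = quantify_band(marker.astype(float), marker, p, band)
        assert (
            q.positive_area_inside_um2 + q.positive_area_band_um2
            <= p.area_um2 + band.area_um2 + 1e-9
        )


class TestCountMicroglia:
    def test_no_somata(self):
        mask = rasterized_disk((80, 80), 40, 40, 10)
        p = detect_plaques(mask, 1.0)[0]
        band = band_mask(p, 30.0, mask.shape, 1.0)
        counts = count_plaque_microglia([], [p], [band])
        assert counts[0].n_within == 0 and counts[0].n_around == 0

    def test_soma_on_outline_counts_as_within(self):
        mask = rasterized_disk((80, 80), 40, 40, 10)
        p = detect_plaques(mask, 1.0)[0]
        band = band_mask(p, 30.0, mask.shape, 1.0)
        counts = count_plaque_microglia([(40.0, 50.0)], [p], [band])  # outline pixel
        assert counts[0].n_within == 1 and counts[0].n_around == 0

    def test_annulus_soma_counts_as_around(self):
        mask = rasterized_disk((100, 100), 50, 50, 10)
        p = detect_plaques(mask, 1.0)[0]
        band = band_mask(p, 30.0, mask.shape, 1.0)
        counts = count_plaque_microglia([(50.0, 75.0)], [p], [band])
        assert counts[0].n_around == 1

    def test_shared_band_assigned_to_nearest_outline(self):
        mask = np.zeros((100, 180), bool)
        mask |= rasterized_disk(mask.shape, 50, 50, 10)
        mask |= rasterized_disk(mask.shape, 50, 120, 10)
        plaques = detect_plaques(mask, 1.0)
        bands = [band_mask(p, 30.0, mask.shape, 1.0) for p in plaques]
        counts = count_plaque_microglia([(50.0, 82.0)], plaques, bands)
        # 82 is 22 um from plaque-0 outline, 28 um from plaque-1 outline
        assert counts[0].n_around == 1
        assert counts[1].n_around == 0

    def test_detect_somata_respects_min_area(self):
        mask = np.zeros((60, 60), bool)
        mask |= rasterized_disk(mask.shape, 20, 20, 4)  # ~50 um^2 at 1 um/px
        mask[40, 40] = True  # 1 um^2 speck
        somata = detect_somata(mask, 1.0, soma_min_area_um2=20.0)
        assert len(somata) == 1
        assert somata[0][0] == pytest.approx(20.0, abs=0.5)


class TestDiameterNeuriteRelation:
    def fake_plaques(self, diameters):
        mask = np.zeros((400, 60), bool)
        for i, d in enumerate(diameters):
            mask |= rasterized_disk(mask.shape, 40 + 60 * i, 30, d / 2)
        return detect_plaques(mask, 1.0)

    def test_strictly_increasing_counts_give_rho_one(self):
        plaques = self.fake_plaques([12, 16, 20, 24, 28])
        r, rho, n = diameter_neurite_relation(plaques, [1, 2, 4, 8, 16])
        assert rho == pytest.approx(1.0)
        assert n == 5

    def test_constant_counts_yield_nan_with_warning(self):
        plaques = self.fake_plaques([12, 16, 20])
        with pytest.warns(UserWarning, match="zero variance"):
            r, rho, _ = diameter_neurite_relation(plaques, [3, 3, 3])
        assert np.isnan(r)

    def test_fewer_than_three_plaques_rejected(self):
        plaques = self.fake_plaques([12, 16])
        with pytest.raises(ValueError, match="at least 3"):
            diameter_neurite_relation(plaques, [1, 2])
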