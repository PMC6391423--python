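"""Halo assay: annulus area, normalization, plate-image measurement."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from microhet import (colony_fluorescence, halo_area, measure_plate_image,
                      normalize_halo, score_halo_table)


def _rasterized_annulus_area(colony_d_mm, halo_d_mm, px_per_mm=100):
    """Pixel-count oracle for the annulus area."""
    r_out = halo_d_mm / 2 * px_per_mm
    r_in = colony_d_mm / 2 * px_per_mm
    n = int(2 * r_out) + 4
    yy, xx = np.mgrid[:n, :n]
    c = (n - 1) / 2
    rr = np.hypot(yy - c, xx - c)
    inside = (rr <= r_out) & (rr > r_in)
    return inside.sum() / px_per_mm ** 2


def _synthetic_plate(colony_d_mm, halo_d_mm, scale=0.1, size=121,
                     lawn=180.0, clearing=60.0, colony=90.0, noise=0.0, seed=0):
    yy, xx = np.mgrid[:size, :size]
    c = (size - 1) / 2
    rr = np.hypot(yy - c, xx - c)
    img = np.full((size, size), lawn)
    img[rr <= halo_d_mm / 2 / scale] = clearing
    img[rr <= colony_d_mm / 2 / scale] = colony
    if noise:
        img += np.random.default_rng(seed).normal(0, noise, img.shape)
    return img


class TestHaloArea:
    def test_no_halo_gives_zero(self):
        assert halo_area(3.0, 3.0) == 0.0

    def test_annulus_formula(self):
        assert halo_area(2.0, 4.0) == pytest.approx(3 * math.pi)

    def test_zero_colony_gives_full_disk(self):
        assert halo_area(0.0, 6.0) == pytest.approx(math.pi / 4 * 36)

    def test_halo_smaller_than_colony_raises(self):
        with pytest.raises(ValueError):
            halo_area(5.0, 4.0)

    def test_matches_pixel_count_oracle_on_random_geometries(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            colony = rng.uniform(0.5, 3.0)
            halo = colony + rng.uniform(0.5, 4.0)
            if halo < 0.4:  # keep radius >= 20 px at 100 px/mm
                continue
            analytic = halo_area(colony, halo)
            oracle = _rasterized_annulus_area(colony, halo)
            assert analytic == pytest.approx(oracle, rel=0.01)

    @settings(deadline=None, max_examples=50)
    @given(st.floats(0.1, 5.0), st.floats(0.0, 5.0), st.floats(0.01, 5.0))
    def test_monotone_in_both_diameters(self, colony, extra, more):
        a = halo_area(colony, colony + extra)
        assert halo_area(colony, colony + extra + more) > a
        if colony + extra >= colony + more > 0 and colony - 0 >= 0:
            pass  # colony monotonicity covered below
        smaller_colony = colony * 0.5
        assert halo_area(smaller_colony, colony + extra) >= a


class TestNormalize:
    def test_self_normalization_is_one(self):
        assert normalize_halo(12.34, 12.34) == 1.0

    def test_zero_area_non_producer(self):
        assert normalize_halo(0.0, 10.0) == 0.0

    def test_nonpositive_reference_raises(self):
        with pytest.raises(ValueError):
            normalize_halo(1.0, 0.0)

    def test_table_scoring(self):
        df = pd.DataFrame({
            "strain_id": ["WT", "mutA", "nonproducer"],
            "colony_diameter_mm": [2.0, 2.0, 2.0],
            "halo_diameter_mm": [4.0, 6.0, 2.0],
        })
        out = score_halo_table(df, "WT")
        assert out.loc[0, "normalized_activity"] == pytest.approx(1.0)
        assert out.loc[1, "normalized_activity"] == pytest.approx(32 / 12)
        assert out.loc[2, "normalized_activity"] == 0.0


class TestPlateImage:
    def test_constructed_plate_diameters(self):
        img = _synthetic_plate(4.0, 8.0, scale=0.1)
        d = measure_plate_image(img, 0.1)
        assert not d.no_halo
        assert d.colony_diameter == pytest.approx(4.0, abs=0.2)
        assert d.halo_diameter == pytest.approx(8.0, abs=0.2)

    def test_uniform_lawn_flags_no_halo(self):
        img = np.full((101, 101), 180.0)
        img += np.random.default_rng(0).normal(0, 2, img.shape)
        assert measure_plate_image(img, 0.1).no_halo

    def test_scale_invariance(self):
        a = measure_plate_image(_synthetic_plate(4.0, 8.0, scale=0.1, size=121), 0.1)
        b = measure_plate_image(
            _synthetic_plate(4.0, 8.0, scale=0.05, size=241), 0.05)
        assert b.colony_diameter == pytest.approx(a.colony_diameter, rel=0.02)
        assert b.halo_diameter == pytest.approx(a.halo_diameter, rel=0.02)

    def test_end_to_end_normalization_near_one(self):
        img = _synthetic_plate(2.0, 4.0, scale=0.1, size=81, noise=2.0)
        ref = _synthetic_plate(2.0, 4.0, scale=0.1, size=81, noise=2.0, seed=5)
        dm = measure_plate_image(img, 0.1)
        dr = measure_plate_image(ref, 0.1)
        ratio = normalize_halo(halo_area(dm.colony_diameter, dm.halo_diameter),
                               halo_area(dr.colony_diameter, dr.halo_diameter))
        assert ratio == pytest.approx(1.0, abs=0.05)

    def test_random_geometries_within_five_percent(self):
        # 0.05 mm/px so the 5% tolerance spans >1 px even for small colonies
        rng = np.random.default_rng(3)
        for _ in range(10):
            colony = rng.uniform(1.5, 3.0)
            halo = colony + rng.uniform(1.5, 4.0)
            img = _synthetic_plate(colony, halo, scale=0.05,
                                   size=2 * int(halo / 0.05) + 41)
            d = measure_plate_image(img, 0.05)
            assert d.colony_diameter == pytest.approx(colony, rel=0.05)
            assert d.halo_diameter == pytest.approx(halo, rel=0.05)


class TestColonyFluorescence:
    @staticmethod
    def _plate(n_colonies=50, intensity=500.0, background=100.0, seed=0):
        rng = np.random.default_rng(seed)
        img = np.full((400, 400), background)
        yy, xx = np.mgrid[:400, :400]
        placed = 0
        centers = []
        while placed < n_colonies:
            cy, cx = rng.uniform(15, 385, 2)
            if all(np.hypot(cy - a, cx - b) > 25 for a, b in centers):
                img[np.hypot(yy - cy, xx - cx) <= 8] = intensity
                centers.append((cy, cx))
                placed += 1
        img += rng.normal(0, 3, img.shape)
        return img

    def test_uniform_colonies_counted_and_measured(self):
        res = colony_fluorescence(self._plate(), retention_threshold=200.0)
        assert res.n_colonies == 50
        assert np.allclose(res.mean_intensities, 400.0, atol=20.0)
        assert res.retention_fraction == 1.0

    def test_blank_plate_warns_zero_colonies(self):
        img = np.full((100, 100), 100.0)
        img += np.random.default_rng(1).normal(0, 3, img.shape)
        res = colony_fluorescence(img)
        assert res.n_colonies == 0 and res.warning

    def test_histogram_counts_sum_to_colony_count(self):
        res = colony_fluorescence(self._plate(n_colonies=30))
        assert res.histogram_counts.sum() == res.n_colonies
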