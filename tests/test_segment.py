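"""Ridge enhancement, skeleton extraction, cisterna/polygon segmentation."""

import numpy as np
import pytest
from scipy import ndimage as ndi

from erquant.phasecong import phase_congruency_ft
from erquant.segment import (PixelSkeleton, hysteresis_skeleton,
                             segment_cisternae, segment_polygons,
                             shape_metrics)


def _ridge_image(amplitude=1.0, sigma=2.0, shape=(64, 128)):
    yy = np.arange(shape[0])[:, None]
    img = amplitude * np.exp(-(yy - shape[0] // 2) ** 2 / (2 * sigma ** 2))
    return np.broadcast_to(img, shape).copy()


class TestFeatureType:
    def test_values_bounded_and_ridge_maximal(self):
        img = _ridge_image()
        ft = phase_congruency_ft(img).ft
        assert ft.min() >= 0.0 and ft.max() <= 1.0
        crest = ft[32, 40:88].mean()
        flank = ft[26, 40:88].mean()
        assert crest > flank
        assert crest > 0.8          # bright ridge maps near 1

    def test_intensity_independence(self):
        img = _ridge_image() + 0.05
        ft1 = phase_congruency_ft(img).ft
        ft2 = phase_congruency_ft(2.0 * img).ft
        on = ft1 > 0.3
        assert np.abs(ft1[on] - ft2[on]).max() < 0.01

    def test_step_edge_scores_below_ridge(self):
        ridge = _ridge_image()
        step = np.zeros((64, 128))
        step[32:, :] = 1.0
        ft_r = phase_congruency_ft(ridge).ft
        ft_s = phase_congruency_ft(step).ft
        # edges sit near the 0.5 phase angle, ridges near 1
        assert ft_r[32, 40:88].mean() > ft_s[32, 40:88].mean() + 0.2

    def test_constant_frame_warns_and_returns_zero(self):
        with pytest.warns(UserWarning, match="constant"):
            ft = phase_congruency_ft(np.full((32, 32), 1.0))
        assert np.all(ft.ft == 0)


class TestHysteresisSkeleton:
    def test_shallow_enclosed_valley_not_flooded(self):
        """A 0.04-deep basin enclosed by ridge lines (appressed-tubule
        geometry) is zeroed by the h-minimum rule, so hysteresis keeps
        the enclosed face open instead of flooding it solid."""
        ft = np.zeros((40, 40))
        ft[12:28, 12:28] = 0.86      # interior basin, depth 0.04 < hmin
        ft[12, 12:28] = ft[27, 12:28] = 0.9    # enclosing ridge ring
        ft[12:28, 12] = ft[12:28, 27] = 0.9
        sk = hysteresis_skeleton(ft, lo=0.3, hi=0.5, hmin=0.05)
        # interior was zeroed: the skeleton is a ring enclosing a face
        assert not sk.pixels[20, 20]
        from erquant.segment import segment_polygons
        polys = segment_polygons(sk, None, np.ones((40, 40), bool), 40.0)
        assert len(polys) == 1
        # without the h-minimum rule the basin floods and no face is left
        sk0 = hysteresis_skeleton(ft, lo=0.3, hi=0.5, hmin=0.0)
        polys0 = segment_polygons(sk0, None, np.ones((40, 40), bool), 40.0)
        assert len(polys0) == 0

    def test_hysteresis_keeps_only_strong_connected_region(self):
        ft = np.full((30, 30), 0.4)
        ft[2:5, 2:5] = 0.0           # detach a border region
        ft[10:14, 10:14] = 0.6       # strong blob
        ft[20:22, 2:4] = 0.35        # weak island (isolated by zeros)
        ft[18:24, :] = 0.0
        ft[:, 6:8] = 0.0
        sk = hysteresis_skeleton(ft, lo=0.3, hi=0.5, hmin=0.0)
        ys, xs = np.nonzero(sk.pixels)
        assert len(ys) > 0
        assert ys.max() < 18         # weak island did not survive

    def test_bar_thins_to_centreline(self):
        ft = np.zeros((20, 40))
        ft[9:12, 5:35] = 0.9
        sk = hysteresis_skeleton(ft, 0.3, 0.5, hmin=0.0)
        ys, xs = np.nonzero(sk.pixels)
        # centreline within the bar, one pixel per column (thin)
        assert set(ys) <= {9, 10, 11}
        assert xs.min() >= 5 and xs.max() <= 34
        assert len(xs) == len(set(xs))

    def test_skeleton_thinness_enforced(self, scene):
        stack, _ = scene
        ft = phase_congruency_ft(stack.data[0, 0])
        sk = hysteresis_skeleton(ft)
        p = sk.pixels
        assert not (p[:-1, :-1] & p[1:, :-1] & p[:-1, 1:] & p[1:, 1:]).any()

    def test_bad_thresholds_rejected(self):
        with pytest.raises(ValueError):
            hysteresis_skeleton(np.zeros((8, 8)), lo=0.5, hi=0.3)


class TestCisternae:
    def test_square_sheet_area_and_circularity(self):
        # 2 µm x 2 µm uniform square at 40 nm pixels = 50 x 50 px
        img = np.zeros((100, 100))
        img[25:75, 25:75] = 0.35
        img = ndi.gaussian_filter(img, 1.5)
        cs = segment_cisternae(img, None, fwhm_max_px=8,
                               min_area_um2=0.3, pixel_size_nm=40.0)
        assert len(cs) == 1
        row = cs.table.iloc[0]
        assert row["area_um2"] == pytest.approx(4.0, rel=0.05)
        assert row["circularity"] == pytest.approx(np.pi / 4, rel=0.12)

    def test_tubule_only_image_has_no_cisternae(self, scene):
        stack, truth = scene
        cs = segment_cisternae(stack.data[0, 0], None, fwhm_max_px=12,
                               min_area_um2=0.3, pixel_size_nm=25.0)
        assert len(cs) == 0

    def test_small_disc_becomes_punctum_not_cisterna(self):
        img = np.zeros((80, 80))
        yy, xx = np.mgrid[0:80, 0:80]
        # area 0.2 µm² at 40 nm px -> radius ~6.3 px, below the 0.3 cut
        img[(yy - 40) ** 2 + (xx - 40) ** 2 <= 6.3 ** 2] = 0.4
        img = ndi.gaussian_filter(img, 1.0)
        cs = segment_cisternae(img, None, fwhm_max_px=5,
                               min_area_um2=0.3, pixel_size_nm=40.0)
        assert len(cs) == 0
        assert len(cs.puncta) == 1
        assert np.allclose(cs.puncta[0], (40, 40), atol=2)


class TestPolygons:
    def test_closed_loop_gives_one_polygon(self):
        sk = np.zeros((40, 40), bool)
        sk[10, 10:30] = sk[29, 10:30] = True
        sk[10:30, 10] = sk[10:30, 29] = True
        mask = np.ones((40, 40), bool)
        ps = segment_polygons(PixelSkeleton(sk), None, mask, 40.0)
        assert len(ps) == 1
        interior = (ps.labels > 0).sum()
        assert interior == 18 * 18

    def test_broken_loop_gives_no_polygon(self):
        sk = np.zeros((40, 40), bool)
        sk[10, 10:30] = sk[29, 10:30] = True
        sk[10:30, 10] = True          # right side missing
        mask = np.ones((40, 40), bool)
        ps = segment_polygons(PixelSkeleton(sk), None, mask, 40.0)
        assert len(ps) == 0


class TestShapeMetrics:
    def test_disc_is_round_smooth_and_solid(self):
        yy, xx = np.mgrid[0:101, 0:101]
        disc = (yy - 50) ** 2 + (xx - 50) ** 2 <= 40 ** 2
        m = shape_metrics(disc, 1000.0)
        assert m["circularity"] == pytest.approx(1.0, abs=0.05)
        assert m["elongation"] == pytest.approx(0.0, abs=0.03)
        assert m["roughness"] == pytest.approx(1.0, abs=0.03)

    def test_two_to_one_ellipse_elongation(self):
        yy, xx = np.mgrid[0:101, 0:201]
        ell = ((yy - 50) / 25.0) ** 2 + ((xx - 100) / 50.0) ** 2 <= 1.0
        m = shape_metrics(ell, 1000.0)
        assert m["elongation"] == pytest.approx(0.5, abs=0.03)

    def test_square_is_fully_solid(self):
        sq = np.zeros((40, 40), bool)
        sq[10:30, 10:30] = True
        m = shape_metrics(sq, 1000.0)
        assert m["solidity"] == pytest.approx(1.0, abs=0.01)

    def test_single_pixel_region_flagged_nan(self):
        reg = np.zeros((10, 10), bool)
        reg[5, 5] = True
        m = shape_metrics(reg, 40.0)
        assert np.isnan(m["major_axis_um"])

    def test_empty_region_rejected(self):
        with pytest.raises(ValueError):
            shape_metrics(np.zeros((5, 5), bool), 40.0)
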