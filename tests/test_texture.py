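"""GLCM construction and texture metrics, with a brute-force oracle."""

import numpy as np
import pandas as pd
import pytest

from erquant.segment import CisternaSet
from erquant.texture import (GLCM, aggregate_textures, build_glcm,
                             glcm_metrics)

_OFF = [(-1, -1), (-1, 0), (-1, 1), (0, 1)]


def brute_force_glcm(region, binned, distance, n_bins):
    """Exhaustive pair enumeration oracle (symmetric, region-pure)."""
    acc = np.zeros((n_bins, n_bins), dtype=int)
    h, w = region.shape
    for y in range(h):
        for x in range(w):
            if not region[y, x]:
                continue
            for dy, dx in _OFF:
                yy, xx = y + dy * distance, x + dx * distance
                if 0 <= yy < h and 0 <= xx < w and region[yy, xx]:
                    a, b = binned[y, x], binned[yy, xx]
                    acc[a, b] += 1
                    acc[b, a] += 1
    return acc / acc.sum()


class TestGLCM:
    @pytest.mark.parametrize("seed,distance", [(0, 1), (1, 1), (2, 2),
                                               (3, 3)])
    def test_equals_brute_force_on_small_regions(self, seed, distance):
        rng = np.random.default_rng(seed)
        frame = rng.random((16, 16))
        region = rng.random((16, 16)) > 0.25
        region[0, :2] = True            # guarantee some pairs
        region[1, :2] = True
        g = build_glcm(region, frame, distance_px=distance, n_bins=8,
                       intensity_range=(0.0, 1.0))
        binned = np.clip((frame * 8).astype(int), 0, 7)
        ref = brute_force_glcm(region, binned, distance, 8)
        np.testing.assert_allclose(g.p, ref, atol=1e-12)

    def test_constant_region_single_diagonal_entry(self):
        frame = np.full((10, 10), 0.5)
        g = build_glcm(np.ones((10, 10), bool), frame, 1, 32,
                       intensity_range=(0.0, 1.0))
        k = int(0.5 * 32)
        assert g.p[k, k] == pytest.approx(1.0)
        assert g.p.sum() == pytest.approx(1.0)

    def test_checkerboard_mass_at_off_diagonal(self):
        yy, xx = np.mgrid[0:8, 0:8]
        frame = ((yy + xx) % 2).astype(float)
        g = build_glcm(np.ones((8, 8), bool), frame, 1, 8,
                       intensity_range=(0.0, 1.0))
        a, b = 0, 7
        # N and E neighbours alternate; diagonals match -> mixed mass
        assert g.p[a, b] == g.p[b, a]            # symmetry
        assert g.p[a, b] > 0
        np.testing.assert_allclose(g.p, g.p.T)

    def test_probabilities_sum_to_one(self, rng):
        frame = rng.random((20, 20))
        region = rng.random((20, 20)) > 0.3
        g = build_glcm(region, frame, 1, 32, intensity_range=(0, 1))
        assert g.p.sum() == pytest.approx(1.0)
        assert (g.p >= 0).all()

    def test_rotation_invariance(self, rng):
        frame = rng.random((16, 16))
        region = np.ones((16, 16), bool)
        m1 = glcm_metrics(build_glcm(region, frame, 1, 8,
                                     intensity_range=(0, 1)))
        m2 = glcm_metrics(build_glcm(region, np.rot90(frame), 1, 8,
                                     intensity_range=(0, 1)))
        assert m1.contrast == pytest.approx(m2.contrast, rel=1e-9)
        assert m1.energy == pytest.approx(m2.energy, rel=1e-9)
        assert m1.homogeneity == pytest.approx(m2.homogeneity, rel=1e-9)

    def test_no_valid_pairs_rejected(self):
        region = np.zeros((9, 9), bool)
        region[0, 0] = region[8, 8] = True
        with pytest.raises(ValueError, match="pairs"):
            build_glcm(region, np.random.default_rng(0).random((9, 9)),
                       1, 8)


class TestMetrics:
    def test_single_diagonal_entry_metrics(self):
        p = np.zeros((32, 32))
        p[5, 5] = 1.0
        m = glcm_metrics(GLCM(p=p, n_bins=32, offset_distance_px=1,
                              n_pairs=100))
        assert m.contrast == 0.0
        assert m.homogeneity == 1.0
        assert m.energy == 1.0
        assert np.isnan(m.correlation)      # sigma = 0 is undefined

    def test_uniform_glcm_energy(self):
        n = 8
        p = np.full((n, n), 1.0 / n ** 2)
        m = glcm_metrics(GLCM(p=p, n_bins=n, offset_distance_px=1,
                              n_pairs=100))
        assert m.energy == pytest.approx(1.0 / n ** 2)

    def test_two_cell_offset_homogeneity(self):
        n = 16
        d = 3
        p = np.zeros((n, n))
        p[2, 2 + d] = p[2 + d, 2] = 0.5
        m = glcm_metrics(GLCM(p=p, n_bins=n, offset_distance_px=1,
                              n_pairs=10))
        assert m.homogeneity == pytest.approx(1.0 / (1 + d))
        assert m.contrast == pytest.approx(d ** 2 / (n - 1) ** 2)


class TestAggregation:
    def _cisternae(self, frames):
        labels = np.zeros((16, 16 * len(frames)), np.int32)
        frame = np.zeros((16, 16 * len(frames)))
        for i, f in enumerate(frames):
            labels[:, 16 * i:16 * (i + 1)][1:-1, 1:-1] = i + 1
            frame[:, 16 * i:16 * (i + 1)] = f
        table = pd.DataFrame({"id": np.arange(1, len(frames) + 1)})
        return CisternaSet(labels=labels, table=table), frame

    def test_single_cisterna_modes_agree(self, rng):
        cs, frame = self._cisternae([rng.random((16, 16))])
        a = aggregate_textures(cs, frame, 1, 8, (0, 1),
                               mode="per_cisterna_mean")
        b = aggregate_textures(cs, frame, 1, 8, (0, 1), mode="pooled")
        assert a.contrast == pytest.approx(b.contrast)
        assert a.energy == pytest.approx(b.energy)

    def test_identical_cisternae_modes_agree(self, rng):
        patch = rng.random((16, 16))
        cs, frame = self._cisternae([patch, patch])
        a = aggregate_textures(cs, frame, 1, 8, (0, 1),
                               mode="per_cisterna_mean")
        b = aggregate_textures(cs, frame, 1, 8, (0, 1), mode="pooled")
        assert a.contrast == pytest.approx(b.contrast, rel=1e-9)

    def test_pooled_weighted_toward_larger_cisterna(self, rng):
        # one smooth large region, one rough small region
        labels = np.zeros((24, 48), np.int32)
        labels[1:23, 1:31] = 1          # large
        labels[4:12, 34:42] = 2         # small
        frame = np.zeros((24, 48))
        frame[:, :32] = 0.5
        frame[:, 32:] = rng.random((24, 16))
        cs = CisternaSet(labels=labels,
                         table=pd.DataFrame({"id": [1, 2]}))
        mean_m = aggregate_textures(cs, frame, 1, 8, (0, 1),
                                    mode="per_cisterna_mean")
        pooled = aggregate_textures(cs, frame, 1, 8, (0, 1), mode="pooled")
        # pooled contrast sits between the two and nearer the large
        # (smooth, contrast 0) region than the unweighted mean
        assert pooled.contrast < mean_m.contrast
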