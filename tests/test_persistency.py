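"""Persistency mapping: occupancy, intensity lag maps, anchor nodes."""

import numpy as np
import pytest

from erquant.persistency import (intensity_persistency, persistency_histogram,
                                 persistent_nodes, structure_persistency)
from erquant.stack import ImageStack
from erquant.synth import animate_scene, generate_network_scene


def _movie(frames, dt=0.5, px=40.0):
    return ImageStack(np.asarray(frames, float)[:, None], pixel_size_nm=px,
                      frame_interval_s=dt)


class TestStructurePersistency:
    def test_static_skeleton_sum_mode_counts_window(self):
        s = np.zeros((20, 20), bool)
        s[10, 4:16] = True
        pm = structure_persistency([s] * 12, None, frame_interval_s=0.5,
                                   dilate_px=1, mode="sum")
        assert pm.tubule_s.max() == pytest.approx(12 * 0.5)
        assert pm.tubule_s[10, 10] == pytest.approx(6.0)

    def test_fast_moving_skeleton_never_accumulates(self):
        frames = []
        for t in range(6):
            s = np.zeros((20, 40), bool)
            s[10, 3 + 6 * t:5 + 6 * t] = True   # jumps by > dilation
            frames.append(s)
        pm = structure_persistency(frames, None, 0.5, dilate_px=1,
                                   mode="sum")
        assert pm.tubule_s.max() <= 2 * 0.5 + 1e-9

    def test_diff_mode_depends_only_on_endpoints(self):
        a = np.zeros((10, 10), bool)
        a[5, 2:8] = True
        blank = np.zeros((10, 10), bool)
        # present at both ends, absent between: still scores persistent
        pm = structure_persistency([a, blank, blank, a], None, 1.0,
                                   dilate_px=0, mode="diff")
        assert pm.tubule_s[5, 5] == pytest.approx(4.0)

    def test_sum_mode_is_frame_order_invariant(self, rng):
        frames = [rng.random((12, 12)) > 0.6 for _ in range(6)]
        pm1 = structure_persistency(frames, None, 1.0, dilate_px=0,
                                    mode="sum")
        perm = [frames[i] for i in rng.permutation(6)]
        pm2 = structure_persistency(perm, None, 1.0, dilate_px=0,
                                    mode="sum")
        np.testing.assert_array_equal(pm1.tubule_s, pm2.tubule_s)

    def test_dilation_monotone(self, rng):
        frames = [rng.random((16, 16)) > 0.7 for _ in range(5)]
        maps = [structure_persistency(frames, None, 1.0, dilate_px=d,
                                      mode="sum").tubule_s
                for d in (0, 1, 2)]
        assert np.all(maps[1] >= maps[0])
        assert np.all(maps[2] >= maps[1])


class TestIntensityPersistency:
    def test_static_movie_everything_persists(self):
        frame = np.zeros((24, 24))
        frame[8:16, 8:16] = 1.0
        pm = intensity_persistency(_movie([frame] * 8), lag_frames=3)
        assert pm.persistent_fraction == pytest.approx(1.0)

    def test_transient_structure_not_persistent(self):
        blank = np.zeros((24, 24))
        frame = blank.copy()
        frame[8:16, 8:16] = 1.0
        pm = intensity_persistency(_movie([frame, blank, blank, blank,
                                           blank]), lag_frames=2)
        assert pm.persistent_fraction == pytest.approx(0.0)

    def test_lag_must_be_shorter_than_movie(self):
        with pytest.raises(ValueError):
            intensity_persistency(_movie([np.ones((8, 8))] * 3),
                                  lag_frames=3)


class TestPersistentNodes:
    def test_anchors_present_every_frame_detected_within_one_pixel(self):
        stack, truth = generate_network_scene(
            n_polygons=30, cisterna_fraction=0.0, noise_sd=0.01,
            n_anchors=3, seed=2)
        mov, mt = animate_scene(truth, 10, translation_um_s=(0.0, 0.0),
                                jitter_sd_px=0.0, seed=102)
        det = persistent_nodes(mov, sigma_px=2.5, threshold=0.4)
        for ay, ax in mt.anchor_px:
            d = np.hypot(det["y"] - ay, det["x"] - ax)
            # detections sit on the integer grid; sub-pixel anchor
            # positions add up to ~0.7 px of rounding distance
            assert d.min() <= 1.5

    def test_anchors_recovered_in_moving_network(self):
        stack, truth = generate_network_scene(
            n_polygons=30, cisterna_fraction=0.0, noise_sd=0.01,
            n_anchors=3, seed=2)
        v = 2.5 * 25 / 1000 / 0.41
        mov, mt = animate_scene(truth, 30, translation_um_s=(v * 0.6,
                                                             v * 0.8),
                                jitter_sd_px=0.5, anchor_pin_radius_px=0.0,
                                seed=102)
        det = persistent_nodes(mov, sigma_px=2.5, threshold=0.4)
        for ay, ax in mt.anchor_px:
            d = np.hypot(det["y"] - ay, det["x"] - ax)
            # smoothing over moving neighbours can shift the maximum a
            # few pixels; matching radius FWHM_min as in the pipeline
            assert d.min() <= 5.0

    def test_intermittent_pixel_suppressed_by_median(self):
        blank = np.zeros((24, 24))
        flicker = blank.copy()
        flicker[12, 12] = 1.0
        anchor = blank.copy()
        anchor[5, 5] = 1.0
        frames = [anchor + (flicker if t in (0, 1) else 0)
                  for t in range(7)]
        det = persistent_nodes(_movie(frames), sigma_px=1.0, threshold=0.4)
        assert ((det["y"] == 5) & (det["x"] == 5)).any()
        assert not ((det["y"] == 12) & (det["x"] == 12)).any()

    def test_threshold_one_keeps_only_global_maximum(self):
        frame = np.zeros((24, 24))
        frame[6, 6] = 1.0
        frame[18, 18] = 0.5
        det = persistent_nodes(_movie([frame] * 4), sigma_px=1.0,
                               threshold=0.999)
        assert len(det) == 1
        assert (det.iloc[0]["y"], det.iloc[0]["x"]) == (6, 6)

    def test_too_short_movie_rejected(self):
        with pytest.raises(ValueError):
            persistent_nodes(_movie([np.ones((8, 8))] * 2), sigma_px=1.0)


class TestHistogram:
    def test_density_integrates_to_one(self, rng):
        vals = rng.uniform(0, 10, 500)
        dens, edges = persistency_histogram(vals, window_s=10.0)
        assert np.sum(dens * np.diff(edges)) == pytest.approx(1.0)

    def test_fully_persistent_mass_at_window(self):
        dens, edges = persistency_histogram(np.full(100, 8.0),
                                            window_s=8.0)
        centres = 0.5 * (edges[:-1] + edges[1:])
        assert centres[np.argmax(dens)] == pytest.approx(8.0, abs=0.5)

    def test_bernoulli_occupancy_concentrates_low(self, rng):
        # mean occupancy of p=0.3 over 10 frames ~ 3 frames
        occ = rng.binomial(10, 0.3, 400).astype(float)
        dens, edges = persistency_histogram(occ, window_s=10.0)
        centres = 0.5 * (edges[:-1] + edges[1:])
        mean = np.sum(dens * np.diff(edges) * centres)
        assert mean == pytest.approx(3.0, abs=0.5)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            persistency_histogram(np.array([]), window_s=5.0)
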