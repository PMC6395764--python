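"""Bulge/constriction detection and boundary profiles."""

import numpy as np
import pandas as pd
import pytest
from scipy import ndimage as ndi

from erquant.profiles import (ProfileTrace, aggregate_boundary_profiles,
                              boundary_profile, dual_channel_ratio,
                              extract_trace, find_peaks_troughs)
from erquant.segment import PixelSkeleton
from erquant.graph import skeleton_to_graph


def _trace(y, positions=None, second=None):
    y = np.asarray(y, float)
    pos = np.asarray(positions) if positions is not None \
        else np.arange(len(y)) * 0.05
    inten = np.stack([y] if second is None else [y, np.asarray(second)])
    return ProfileTrace(edge_id=1, positions_um=pos, intensity=inten)


def _straight_edge_graph(img_shape=(40, 120)):
    s = np.zeros(img_shape, bool)
    s[img_shape[0] // 2, 5:-5] = True
    return skeleton_to_graph(PixelSkeleton(s), 50.0)


class TestExtractTrace:
    def test_flat_tube_gives_flat_trace(self):
        g = _straight_edge_graph()
        img = np.zeros((40, 120))
        img[18:23, :] = 1.0
        u, v, k = next(iter(g.g.edges(keys=True)))
        tr = extract_trace(g, u, v, k, img, normal_halfwidth_px=6)
        inner = tr.intensity[0][5:-5]
        assert inner.std() / inner.mean() < 0.01
        assert np.all(np.diff(tr.positions_um) > 0)

    def test_single_bulge_gives_single_interior_maximum(self):
        g = _straight_edge_graph()
        img = np.zeros((40, 120))
        img[18:23, :] = 1.0
        img[16:25, 55:66] = 1.0         # bulge
        img = ndi.gaussian_filter(img, 1.5)
        u, v, k = next(iter(g.g.edges(keys=True)))
        tr = extract_trace(g, u, v, k, img, normal_halfwidth_px=8,
                           node_exclude_px=4)
        peak_pos = np.argmax(tr.intensity[0])
        assert 0 < peak_pos < len(tr.positions_um) - 1

    def test_two_channels_align(self):
        g = _straight_edge_graph()
        img1 = np.random.default_rng(0).random((40, 120))
        img2 = np.random.default_rng(1).random((40, 120))
        u, v, k = next(iter(g.g.edges(keys=True)))
        tr = extract_trace(g, u, v, k, [img1, img2], normal_halfwidth_px=4)
        assert tr.intensity.shape[0] == 2
        assert tr.intensity.shape[1] == len(tr.positions_um)


class TestPeaksTroughs:
    def test_flat_trace_has_no_events(self):
        ps = find_peaks_troughs(_trace(np.full(50, 3.0)))
        assert len(ps.events) == 0

    def test_sine_counts_and_spacing(self):
        # 10% amplitude, period 1 µm over 5 µm: 5 peaks, 5 troughs
        x = np.linspace(0, 5, 501)
        y = 1.0 + 0.1 * np.sin(2 * np.pi * (x - 0.25))
        ps = find_peaks_troughs(_trace(y, positions=x))
        ev = ps.events
        assert (ev["kind"] == "peak").sum() == 5
        assert (ev["kind"] == "trough").sum() >= 4  # end troughs clipped
        spacing = ps.spacings_um("peak")
        np.testing.assert_allclose(spacing, 1.0, atol=0.02)

    def test_prominence_threshold_rejects_small_bump(self):
        y = np.full(100, 1.0)
        y[50] = 1.02                    # 2% prominence < 3% threshold
        ps = find_peaks_troughs(_trace(y), prominence_frac=0.03)
        assert (ps.events["kind"] == "peak").sum() == 0

    def test_events_invariant_to_intensity_scaling(self):
        x = np.linspace(0, 5, 301)
        y = 1.0 + 0.2 * np.sin(2 * np.pi * x) \
            + 0.05 * np.sin(7.3 * 2 * np.pi * x)
        e1 = find_peaks_troughs(_trace(y)).events
        e2 = find_peaks_troughs(_trace(10.0 * y)).events
        pd.testing.assert_frame_equal(
            e1.drop(columns=["height", "prominence"]),
            e2.drop(columns=["height", "prominence"]))

    def test_peaks_and_troughs_alternate(self):
        rng = np.random.default_rng(5)
        y = 1.0 + ndi.gaussian_filter1d(rng.normal(0, 0.3, 400), 5)
        ev = find_peaks_troughs(_trace(y)).events.sort_values("index")
        kinds = ev["kind"].to_list()
        assert all(a != b for a, b in zip(kinds, kinds[1:]))

    def test_imposed_bulges_recovered_exactly(self):
        x = np.linspace(0, 6, 601)
        y = np.full_like(x, 1.0)
        for c in (1.0, 3.0, 5.0):       # 3 bulges, 10% height
            y += 0.1 * np.exp(-(x - c) ** 2 / (2 * 0.08 ** 2))
        ps = find_peaks_troughs(_trace(y, positions=x))
        assert (ps.events["kind"] == "peak").sum() == 3


class TestDualChannel:
    def test_identical_channels(self):
        x = np.linspace(0, 5, 301)
        y = 1.0 + 0.2 * np.sin(2 * np.pi * x)
        tr = _trace(y, positions=x, second=y)
        ev, corr = dual_channel_ratio(tr, find_peaks_troughs(tr))
        assert corr == pytest.approx(1.0)
        peaks = ev[ev["kind"] == "peak"]
        np.testing.assert_allclose(peaks["ratio_ch1_ch2"], 1.0)

    def test_antiphase_channels(self):
        x = np.linspace(0, 5, 301)
        y = 1.0 + 0.2 * np.sin(2 * np.pi * x)
        tr = _trace(y, positions=x, second=y.max() - y)
        _, corr = dual_channel_ratio(tr, find_peaks_troughs(tr))
        assert corr == pytest.approx(-1.0)

    def test_reticulon_like_pattern_negative_correlation(self):
        """Troughs of the luminal channel at peaks of the shaper channel."""
        x = np.linspace(0, 8, 401)
        lum = 1.0 + 0.3 * np.sin(2 * np.pi * x / 1.2)
        shaper = 0.8 - 0.25 * np.sin(2 * np.pi * x / 1.2) \
            + 0.02 * np.cos(5 * x)
        tr = _trace(lum, positions=x, second=shaper)
        _, corr = dual_channel_ratio(tr, find_peaks_troughs(tr))
        assert corr < -0.9


class TestBoundaryProfile:
    def _disc(self, r=10, shape=(41, 41)):
        yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
        return (yy - 20) ** 2 + (xx - 20) ** 2 <= r ** 2

    def test_uniform_disc_steps_at_bin_zero(self):
        disc = self._disc()
        frame = disc.astype(float)
        bins, means = boundary_profile(disc, frame, n_bins=5)
        interior = means[bins < 0]
        exterior = means[bins >= 0]
        np.testing.assert_allclose(interior, 1.0)
        np.testing.assert_allclose(exterior, 0.0)

    def test_bright_rim_peaks_at_boundary(self):
        disc = self._disc()
        d_in = ndi.distance_transform_edt(disc)
        frame = np.where(disc & (d_in <= 2), 1.0, np.where(disc, 0.3, 0.0))
        bins, means = boundary_profile(disc, frame, n_bins=6)
        assert bins[np.nanargmax(means)] in (-2, -1, 0)

    def test_colocalised_markers_have_identical_profiles(self):
        labels = self._disc().astype(np.int32)
        frame = labels * 0.8
        _, m1, _ = aggregate_boundary_profiles(labels, frame, n_bins=4)
        _, m2, _ = aggregate_boundary_profiles(labels, 0.4 * frame,
                                               n_bins=4)
        np.testing.assert_allclose(m1, m2)     # normalised profiles
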