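"""Intensity variation along tubules and across cisterna boundaries.

Bulges and constrictions along a tubule show up as peaks and troughs in
the intensity trace integrated normal to the tubule axis.  Events must
clear a minimum height (default 5% of the trace maximum) and prominence
(default 3%); constrictions are found by running the same detector on
the inverted trace.  For dual-channel data the per-event channel ratio
and the Pearson correlation between the aligned traces quantify
in-phase vs anti-phase protein distributions (e.g. a tubule-constricting
protein accumulating exactly where the luminal marker is squeezed out).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy.signal import find_peaks

from .graph import ERGraph


@dataclass
class ProfileTrace:
    edge_id: int
    positions_um: np.ndarray            # strictly increasing arclength
    intensity: np.ndarray               # (n_channels, n_positions)
    width_nm: np.ndarray | None = None  # per position, may be NaN


@dataclass
class PeakSet:
    events: pd.DataFrame     # kind, channel, position_um, height, prominence,
    #                          width_nm
    trace_length_um: float = 0.0

    def density_per_um(self, kind: str | None = None,
                       channel: int | None = None) -> float:
        ev = self.events
        if kind is not None:
            ev = ev[ev["kind"] == kind]
        if channel is not None:
            ev = ev[ev["channel"] == channel]
        if self.trace_length_um <= 0:
            return np.nan
        return len(ev) / self.trace_length_um

    def spacings_um(self, kind: str, channel: int = 0) -> np.ndarray:
        ev = self.events
        ev = ev[(ev["kind"] == kind) & (ev["channel"] == channel)]
        pos = np.sort(ev["position_um"].to_numpy())
        return np.diff(pos)


def extract_trace(graph: ERGraph, u, v, k,
                  frames: list[np.ndarray] | np.ndarray,
                  normal_halfwidth_px: float,
                  node_exclude_px: float = 0.0,
                  width_map: np.ndarray | None = None) -> ProfileTrace:
    """Intensity integrated normal to the tubule axis, per channel.

    The local normal is taken from a ±2-pixel path tangent; intensity is
    sampled by linear interpolation at half-pixel steps over
    ``±normal_halfwidth_px`` and summed.  Pixels within
    ``node_exclude_px`` of either end are dropped (node regions carry
    junction signal, not tubule signal).
    """
    d = graph.g.edges[u, v, k]
    path = np.asarray(d["pixel_path"], dtype=float)
    if len(path) < 3:
        raise ValueError("edge pixel path must have >= 3 pixels")
    if isinstance(frames, np.ndarray) and frames.ndim == 2:
        frames = [frames]

    steps = np.hypot(*np.diff(path, axis=0).T)
    arclen = np.concatenate([[0.0], np.cumsum(steps)])
    keep = np.ones(len(path), dtype=bool)
    if node_exclude_px > 0:
        keep = (arclen >= node_exclude_px) \
            & (arclen <= arclen[-1] - node_exclude_px)
        if not keep.any():
            keep = np.ones(len(path), dtype=bool)

    # tangents from +-2 px along the path
    lo = np.clip(np.arange(len(path)) - 2, 0, len(path) - 1)
    hi = np.clip(np.arange(len(path)) + 2, 0, len(path) - 1)
    tang = path[hi] - path[lo]
    norm = np.hypot(tang[:, 0], tang[:, 1])
    norm[norm == 0] = 1.0
    tang /= norm[:, None]
    normal = np.column_stack([-tang[:, 1], tang[:, 0]])

    offs = np.arange(-normal_halfwidth_px, normal_halfwidth_px + 0.25, 0.5)
    sample_y = path[:, 0][:, None] + normal[:, 0][:, None] * offs[None, :]
    sample_x = path[:, 1][:, None] + normal[:, 1][:, None] * offs[None, :]
    traces = []
    for fr in frames:
        vals = ndi.map_coordinates(np.asarray(fr, float),
                                   [sample_y.ravel(), sample_x.ravel()],
                                   order=1, mode="constant")
        traces.append(vals.reshape(sample_y.shape).sum(axis=1) * 0.5)
    intensity = np.asarray(traces)[:, keep]

    width = None
    if width_map is not None:
        ip = path[keep].astype(int)
        width = np.asarray(width_map)[ip[:, 0], ip[:, 1]]
    px_um = graph.pixel_size_nm / 1000.0
    return ProfileTrace(edge_id=d.get("id", -1),
                        positions_um=arclen[keep] * px_um,
                        intensity=intensity, width_nm=width)


def find_peaks_troughs(trace: ProfileTrace, height_frac: float = 0.05,
                       prominence_frac: float = 0.03) -> PeakSet:
    """Peaks (bulges) and troughs (constrictions) along each channel.

    Thresholds are fractions of each profile's own maximum, so event
    counts are invariant to uniform intensity rescaling.  Same-kind
    runs are reduced to their most extreme member so peaks and troughs
    alternate along the trace.
    """
    if trace.intensity.shape[1] < 3:
        raise ValueError("trace must have >= 3 positions")
    rows = []
    for c in range(trace.intensity.shape[0]):
        y = trace.intensity[c]
        top = y.max()
        if top <= 0:
            continue
        pk, pprop = find_peaks(y, height=height_frac * top,
                               prominence=prominence_frac * top)
        inv = top - y
        tr_, tprop = find_peaks(inv, height=height_frac * top,
                                prominence=prominence_frac * top)
        for idx, h, pr in zip(pk, pprop["peak_heights"],
                              pprop["prominences"]):
            rows.append(("peak", c, idx, h, pr))
        for idx, h, pr in zip(tr_, tprop["peak_heights"],
                              tprop["prominences"]):
            rows.append(("trough", c, idx, y[idx], pr))
    events = pd.DataFrame(rows, columns=["kind", "channel", "index",
                                         "height", "prominence"])
    events = _enforce_alternation(events)
    events["position_um"] = trace.positions_um[events["index"].to_numpy(int)] \
        if len(events) else np.empty(0)
    if trace.width_nm is not None and len(events):
        events["width_nm"] = trace.width_nm[events["index"].to_numpy(int)]
    else:
        events["width_nm"] = np.nan
    length = float(trace.positions_um[-1] - trace.positions_um[0])
    return PeakSet(events=events.reset_index(drop=True),
                   trace_length_um=length)


def _enforce_alternation(events: pd.DataFrame) -> pd.DataFrame:
    """Within each channel keep the most extreme event of same-kind runs."""
    out = []
    for c, ev in events.groupby("channel"):
        ev = ev.sort_values("index")
        kept: list = []
        for _, row in ev.iterrows():
            if kept and kept[-1]["kind"] == row["kind"]:
                prev = kept[-1]
                better = (row["height"] > prev["height"]
                          if row["kind"] == "peak"
                          else row["height"] < prev["height"])
                if better:
                    kept[-1] = row
            else:
                kept.append(row)
        out.extend(kept)
    if not out:
        return events
    return pd.DataFrame(out)


def dual_channel_ratio(trace: ProfileTrace,
                       events: PeakSet) -> tuple[pd.DataFrame, float]:
    """Per-event channel-1/channel-2 ratio and trace cross-correlation.

    A negative correlation reports an anti-phase relationship between
    the two markers along the tubule.
    """
    if trace.intensity.shape[0] < 2:
        raise ValueError("dual_channel_ratio needs a two-channel trace")
    a, b = trace.intensity[0], trace.intensity[1]
    corr = float(np.corrcoef(a, b)[0, 1]) if a.std() > 0 and b.std() > 0 \
        else np.nan
    ev = events.events.copy()
    if len(ev):
        idx = ev["index"].to_numpy(int)
        denom = b[idx]
        ratio = np.where(denom != 0, a[idx] / np.where(denom == 0, 1, denom),
                         np.nan)
        ev["ratio_ch1_ch2"] = ratio
    else:
        ev["ratio_ch1_ch2"] = np.nan
    return ev, corr


def boundary_profile(region: np.ndarray, frame: np.ndarray,
                     n_bins: int = 10) -> tuple[np.ndarray, np.ndarray]:
    """Mean intensity in signed integer EDT bins across a region boundary.

    Bin −1 is the first interior ring, bin 0 the first exterior ring;
    interior bins decrement inwards, exterior bins increment outwards.
    Returns ``(bins, mean_intensity)`` with NaN for empty bins.
    """
    region = np.asarray(region, bool)
    if not region.any():
        raise ValueError("empty region")
    frame = np.asarray(frame, float)
    d_in = ndi.distance_transform_edt(region)
    d_out = ndi.distance_transform_edt(~region)
    binmap = np.where(region, -np.ceil(d_in), np.ceil(d_out) - 1).astype(int)
    bins = np.arange(-n_bins, n_bins)
    means = np.full(len(bins), np.nan)
    for i, b in enumerate(bins):
        sel = binmap == b
        if sel.any():
            means[i] = frame[sel].mean()
    return bins, means


def aggregate_boundary_profiles(labels: np.ndarray, frame: np.ndarray,
                                n_bins: int = 10, normalise: bool = True
                                ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Mean ± SD radial profile across all labelled cisternae."""
    ids = np.unique(labels)
    ids = ids[ids > 0]
    profs = []
    for rid in ids:
        bins, m = boundary_profile(labels == rid, frame, n_bins)
        if normalise and np.nanmax(m) > 0:
            m = m / np.nanmax(m)
        profs.append(m)
    if not profs:
        raise ValueError("no labelled regions")
    profs = np.asarray(profs)
    return (np.arange(-n_bins, n_bins), np.nanmean(profs, axis=0),
            np.nanstd(profs, axis=0))
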