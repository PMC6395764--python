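"""Persistency mapping of static network elements.

Two complementary approaches quantify how long tubules, cisternae and
nodes stay put:

* **Intensity persistency** — the absolute intensity difference over a
  user-defined lag, masked by the Boolean AND of the segmentations at
  both time points; pixels present at both ends with little intensity
  change are persistent.  Summaries are normalised to the total
  segmented area over all frames (Boolean OR).
* **Structure persistency** — segmented skeletons and cisterna masks,
  dilated by FWHM_min/2, are either summed over a time window (graded
  per-pixel occupancy) or differenced between the window's endpoints
  (binary estimate; note a pixel occupied at both ends but vacated in
  between still scores persistent).

Persistent *nodes* (candidate ER–plasma-membrane contact sites, which
tubules and cisternae may transiently slide across) are found from a
temporal median projection of the intensity movie, Gaussian-smoothed in
xy, normalised to [0, 1], and thresholded local maxima.

All durations are reported in seconds (frames × frame interval).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.filters import threshold_otsu

from .stack import ImageStack


@dataclass
class PersistencyMap:
    tubule_s: np.ndarray | None       # per-pixel occupancy duration, seconds
    cisterna_s: np.ndarray | None
    window_s: float
    mode: str                          # "sum" | "diff" | "intensity"
    persistent_fraction: float = np.nan   # persistent px / OR-occupancy px


def intensity_persistency(stack: ImageStack, lag_frames: int,
                          channel: int = 0,
                          diff_frac: float = 0.25) -> PersistencyMap:
    """Sparkes-style persistency from intensity differences over a lag.

    For every frame pair (t, t+lag): a pixel is persistent if it is
    segmented (Otsu) in both frames and |I(t) − I(t+lag)| is below
    ``diff_frac`` of the movie's robust maximum.  The per-pixel count of
    persistent pairs is scaled to seconds; the summary fraction is
    normalised by the OR of all segmentations.
    """
    if lag_frames >= stack.n_frames:
        raise ValueError("lag_frames must be < number of frames")
    movie = stack.data[:, channel]
    top = np.percentile(movie, 99.9)
    masks = np.stack([m > threshold_otsu(m) if np.ptp(m) > 0
                      else np.zeros(m.shape, bool) for m in movie])
    count = np.zeros(movie.shape[1:], dtype=np.int32)
    n_pairs = stack.n_frames - lag_frames
    for t in range(n_pairs):
        both = masks[t] & masks[t + lag_frames]
        quiet = np.abs(movie[t + lag_frames] - movie[t]) < diff_frac * top
        count += (both & quiet)
    occupied = masks.any(axis=0)
    persistent = count == n_pairs
    frac = float(persistent.sum() / occupied.sum()) if occupied.any() \
        else np.nan
    dur = count / n_pairs * (stack.n_frames * stack.frame_interval_s)
    return PersistencyMap(tubule_s=dur, cisterna_s=None,
                          window_s=stack.n_frames * stack.frame_interval_s,
                          mode="intensity", persistent_fraction=frac)


def structure_persistency(skeletons: list[np.ndarray],
                          cisterna_masks: list[np.ndarray] | None,
                          frame_interval_s: float,
                          dilate_px: int = 2, window: int | None = None,
                          mode: str = "sum") -> PersistencyMap:
    """Occupancy persistency from the segmented structures themselves."""
    if mode not in ("sum", "diff"):
        raise ValueError(f"mode must be 'sum' or 'diff', got {mode!r}")
    n = len(skeletons)
    if window is None:
        window = n
    if window > n:
        raise ValueError("window exceeds number of frames")

    def occupancy(masks):
        occ = np.stack([
            ndi.binary_dilation(m, iterations=dilate_px) if dilate_px > 0
            else np.asarray(m, bool) for m in masks[:window]])
        if mode == "sum":
            return occ.sum(axis=0) * frame_interval_s
        return (occ[0] & occ[-1]).astype(float) * (window * frame_interval_s)

    tub = occupancy(skeletons)
    cis = occupancy(cisterna_masks) if cisterna_masks is not None else None
    return PersistencyMap(tubule_s=tub, cisterna_s=cis,
                          window_s=window * frame_interval_s, mode=mode)


def element_persistency(pmap: PersistencyMap,
                        element_pixels: np.ndarray,
                        kind: str = "tubule") -> float:
    """Mean persistency (s) of one element's pixels."""
    grid = pmap.tubule_s if kind == "tubule" else pmap.cisterna_s
    if grid is None:
        return np.nan
    sel = np.asarray(element_pixels)
    if sel.dtype == bool:
        vals = grid[sel]
    else:
        sel = sel.reshape(-1, 2)
        vals = grid[sel[:, 0], sel[:, 1]]
    return float(vals.mean()) if vals.size else np.nan


def persistent_nodes(stack: ImageStack, sigma_px: float,
                     threshold: float = 0.4, channel: int = 0,
                     min_distance_px: int | None = None) -> pd.DataFrame:
    """Candidate anchor points from the temporal median projection.

    A pixel occupied in fewer than half the frames has a near-background
    median and is rejected; smoothing with σ = FWHM_min/2 merges
    single-pixel speckle into blob maxima.  Returns columns y, x, score
    (normalised median intensity at the maximum).
    """
    if stack.n_frames < 3:
        raise ValueError("temporal median needs >= 3 frames")
    med = np.median(stack.data[:, channel], axis=0)
    sm = ndi.gaussian_filter(med, sigma_px)
    rng = np.ptp(sm)
    if rng == 0:
        return pd.DataFrame(columns=["y", "x", "score"])
    norm = (sm - sm.min()) / rng
    if min_distance_px is None:
        min_distance_px = max(int(round(2 * sigma_px)), 1)
    peaks = peak_local_max(norm, min_distance=min_distance_px,
                           threshold_abs=threshold, exclude_border=False)
    return pd.DataFrame({"y": peaks[:, 0], "x": peaks[:, 1],
                         "score": norm[peaks[:, 0], peaks[:, 1]]})


def persistency_histogram(values_s: np.ndarray, window_s: float,
                          n_bins: int = 20) -> tuple[np.ndarray, np.ndarray]:
    """Probability density of per-element mean persistency (seconds)."""
    values_s = np.asarray(values_s, dtype=np.float64)
    values_s = values_s[np.isfinite(values_s)]
    if values_s.size == 0:
        raise ValueError("no persistency values")
    edges = np.linspace(0.0, max(window_s, values_s.max()), n_bins + 1)
    density, edges = np.histogram(values_s, bins=edges, density=True)
    return density, edges
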