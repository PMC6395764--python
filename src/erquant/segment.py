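"""Segmentation of tubule skeleton, cisternae and polygonal regions.

The Feature-Type ridge image is binarised by hysteresis thresholding
(defaults 0.3 / 0.5) after zeroing shallow local minima (h-minima rule,
default depth 0.05) so closely appressed tubules are not merged, then
thinned to a single-pixel skeleton (Zhang–Suen).  Cisternae are
segmented from the intensity image by morphological opening with a disc
of diameter FWHM_max (removing everything tubule-sized) followed by an
active-contour refinement that shrinks each region boundary back onto
the intensity profile; regions below the area cut-off (default 0.3 µm²)
are returned as punctum candidates rather than cisternae.  Polygonal
regions are the enclosed components of the complement of skeleton and
cisternae inside the analysis mask.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy.spatial import ConvexHull
from skimage.filters import threshold_otsu
from skimage.measure import find_contours, regionprops
from skimage.morphology import disk, skeletonize
from skimage.segmentation import morphological_chan_vese

from .phasecong import FeatureTypeImage, phase_congruency_ft  # re-export
from .preprocess import Mask

__all__ = [
    "PixelSkeleton", "CisternaSet", "PolygonSet", "phase_congruency_ft",
    "hysteresis_skeleton", "segment_cisternae", "segment_polygons",
    "shape_metrics",
]


@dataclass
class PixelSkeleton:
    pixels: np.ndarray        # bool (H, W), single-pixel-wide, 8-connected
    frame_index: int = 0

    def __post_init__(self) -> None:
        p = self.pixels
        if p.size and (p[:-1, :-1] & p[1:, :-1] & p[:-1, 1:] & p[1:, 1:]).any():
            raise ValueError("skeleton is not single-pixel-wide "
                             "(2x2 block found)")


@dataclass
class CisternaSet:
    labels: np.ndarray        # int (H, W), 0 = background
    table: pd.DataFrame       # one row per cisterna (shape + intensity)
    puncta: np.ndarray = field(default_factory=lambda: np.empty((0, 2)))
    # (k, 2) centroids of bright objects below the cisterna area cut-off

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class PolygonSet:
    labels: np.ndarray
    table: pd.DataFrame

    def __len__(self) -> int:
        return len(self.table)


def hysteresis_skeleton(ft: FeatureTypeImage | np.ndarray, lo: float = 0.3,
                        hi: float = 0.5, hmin: float = 0.05,
                        frame_index: int = 0) -> PixelSkeleton:
    """Binarise the Feature-Type image and thin to a pixel skeleton.

    Local intensity minima are first identified with an h-minimum
    transform (``hmin`` deep) and set to zero: the shallow enclosed
    valleys between closely appressed tubules would otherwise be
    flooded by the hysteresis fill and merge distinct tubules.
    """
    img = ft.ft if isinstance(ft, FeatureTypeImage) else np.asarray(ft, float)
    if not lo < hi:
        raise ValueError("lo must be < hi")
    work = img.copy()
    if hmin > 0 and np.ptp(work) > 0:
        # h-minimum transform: fill every basin by at most hmin; the
        # raised pixels are the shallow local minima — zeroing them
        # keeps hysteresis from flooding across the faint valleys
        # between closely appressed tubules
        from skimage.morphology import reconstruction
        filled = reconstruction(work + hmin, work, method="erosion")
        work[filled > work + 1e-12] = 0.0

    strong = work >= hi
    weak = work >= lo
    lab, _ = ndi.label(weak, structure=np.ones((3, 3), int))
    keep = np.unique(lab[strong])
    keep = keep[keep > 0]
    binary = np.isin(lab, keep)
    thin = skeletonize(binary, method="zhang")
    thin = _break_blocks(thin)
    return PixelSkeleton(pixels=thin, frame_index=frame_index)


def _break_blocks(skel: np.ndarray) -> np.ndarray:
    """Remove residual 2x2 blocks left by thinning without breaking paths.

    From each block the corner whose outward-diagonal neighbour is empty
    is deleted; every outward 4-neighbour of that corner stays
    8-connected through the remaining three block pixels.
    """
    s = skel.copy()
    for _ in range(8):
        blocks = s[:-1, :-1] & s[1:, :-1] & s[:-1, 1:] & s[1:, 1:]
        ys, xs = np.nonzero(blocks)
        if len(ys) == 0:
            break
        for y, x in zip(ys, xs):
            if not (s[y, x] & s[y + 1, x] & s[y, x + 1] & s[y + 1, x + 1]):
                continue
            corners = ((y, x, y - 1, x - 1), (y, x + 1, y - 1, x + 2),
                       (y + 1, x, y + 2, x - 1), (y + 1, x + 1, y + 2, x + 2))
            chosen = None
            for cy, cx, dy, dx in corners:
                if (dy < 0 or dx < 0 or dy >= s.shape[0] or dx >= s.shape[1]
                        or not s[dy, dx]):
                    chosen = (cy, cx)
                    break
            if chosen is None:
                chosen = (y, x)
            s[chosen] = False
    return s


def segment_cisternae(frame: np.ndarray, skeleton: PixelSkeleton | None,
                      fwhm_max_px: float, min_area_um2: float,
                      pixel_size_nm: float,
                      refine_iters: int = 50) -> CisternaSet:
    """Segment sheet-like cisternae by opening + active-contour refinement."""
    frame = np.asarray(frame, dtype=np.float64)
    px_um2 = (pixel_size_nm / 1000.0) ** 2
    min_area_px = min_area_um2 / px_um2
    radius = max(int(round(fwhm_max_px / 2.0)), 1)
    opened = ndi.grey_opening(frame, footprint=disk(radius))

    empty = CisternaSet(labels=np.zeros(frame.shape, dtype=np.int32),
                        table=_empty_region_table())
    if frame.max() <= 0 or opened.max() < 0.1 * frame.max():
        return empty
    thr = threshold_otsu(opened) if np.ptp(opened) > 0 else np.inf
    binary = opened > thr
    if not binary.any():
        return empty

    lab0, n0 = ndi.label(binary)
    out = np.zeros(frame.shape, dtype=np.int32)
    puncta = []
    next_id = 1
    pad = radius + 2
    for region in regionprops(lab0):
        if region.area < 0.1 * min_area_px and region.area < 20:
            continue
        y0, x0, y1, x1 = region.bbox
        y0, x0 = max(y0 - pad, 0), max(x0 - pad, 0)
        y1 = min(y1 + pad, frame.shape[0])
        x1 = min(x1 + pad, frame.shape[1])
        crop = frame[y0:y1, x0:x1]
        init = (lab0[y0:y1, x0:x1] == region.label)
        refined = morphological_chan_vese(crop, num_iter=refine_iters,
                                          init_level_set=init, smoothing=1)
        refined = refined.astype(bool)
        # keep the refined component that overlaps the seed
        rl, _ = ndi.label(refined)
        hits = np.unique(rl[init & refined])
        hits = hits[hits > 0]
        if len(hits) == 0:
            refined = init
        else:
            refined = np.isin(rl, hits)
        refined = ndi.binary_fill_holes(refined)
        area = refined.sum()
        cy, cx = ndi.center_of_mass(refined)
        if area * px_um2 < min_area_um2:
            puncta.append((cy + y0, cx + x0))
            continue
        target = out[y0:y1, x0:x1]
        target[refined & (target == 0)] = next_id
        next_id += 1

    table = _region_table(out, frame, pixel_size_nm)
    return CisternaSet(labels=out, table=table,
                       puncta=np.asarray(puncta).reshape(-1, 2))


def segment_polygons(skeleton: PixelSkeleton, cisternae: CisternaSet | None,
                     mask: Mask | np.ndarray, pixel_size_nm: float,
                     min_area_px: int = 4) -> PolygonSet:
    """Enclosed polygonal regions of the network.

    Components (4-connected, so the 8-connected skeleton is watertight)
    of ``mask − skeleton − cisternae`` that do not touch the mask
    boundary or the image border.  Components below ``min_area_px``
    pixels are raster pockets at junctions, far below the psf area,
    and are dropped.
    """
    region = mask.region if isinstance(mask, Mask) else np.asarray(mask, bool)
    free = region & ~skeleton.pixels
    if cisternae is not None:
        free &= cisternae.labels == 0
    lab, n = ndi.label(free, structure=ndi.generate_binary_structure(2, 1))
    if n:
        border = ~region
        border[0, :] = border[-1, :] = border[:, 0] = border[:, -1] = True
        # components 4-adjacent to the outside are open, not polygons
        touching = np.unique(lab[ndi.binary_dilation(
            border, ndi.generate_binary_structure(2, 1)) & (lab > 0)])
        relabel = np.zeros(n + 1, dtype=np.int32)
        counts = np.bincount(lab.ravel(), minlength=n + 1)
        keep = [k for k in range(1, n + 1)
                if k not in set(touching) and counts[k] >= min_area_px]
        for new, old in enumerate(keep, start=1):
            relabel[old] = new
        lab = relabel[lab]
    table = _region_table(lab, None, pixel_size_nm)
    return PolygonSet(labels=lab.astype(np.int32), table=table)


def shape_metrics(region_mask: np.ndarray, pixel_size_nm: float,
                  intensity: np.ndarray | None = None) -> dict:
    """Shape metric vector for a single labelled region, physical units.

    Definitions used throughout the package: perimeter is the polygonal
    sub-pixel boundary length; ``solidity`` = area / convex area;
    ``elongation`` = 1 − minor/major axis; ``circularity`` =
    4π·area/perimeter²; ``roughness`` = perimeter / convex perimeter.
    """
    region_mask = np.asarray(region_mask, bool)
    if not region_mask.any():
        raise ValueError("empty region")
    px_um = pixel_size_nm / 1000.0
    props = regionprops(region_mask.astype(np.uint8))[0]
    area = props.area * px_um ** 2
    cy, cx = props.centroid

    contour = _outer_contour(region_mask)
    if contour is None or props.area < 4:
        out = dict(area_um2=area, perimeter_um=np.nan, major_axis_um=np.nan,
                   minor_axis_um=np.nan, solidity=np.nan, elongation=np.nan,
                   circularity=np.nan, roughness=np.nan,
                   centroid_y=cy, centroid_x=cx)
    else:
        per = _polyline_length(contour) * px_um
        try:
            hull = ConvexHull(contour)
            convex_per = _polyline_length(
                np.vstack([contour[hull.vertices], contour[hull.vertices[:1]]]),
                closed=False) * px_um
        except Exception:
            convex_per = per
        major = props.axis_major_length * px_um
        minor = props.axis_minor_length * px_um
        out = dict(
            area_um2=area,
            perimeter_um=per,
            major_axis_um=major,
            minor_axis_um=minor,
            solidity=props.solidity,
            elongation=1.0 - minor / major if major > 0 else np.nan,
            circularity=4.0 * np.pi * area / per ** 2 if per > 0 else np.nan,
            roughness=per / convex_per if convex_per > 0 else np.nan,
            centroid_y=cy, centroid_x=cx)
    if intensity is not None:
        vals = np.asarray(intensity, float)[region_mask]
        out.update(mean_intensity=float(vals.mean()),
                   max_intensity=float(vals.max()),
                   sd_intensity=float(vals.std()))
    return out


def _outer_contour(mask: np.ndarray) -> np.ndarray | None:
    """Sub-pixel outer boundary, smoothed to suppress raster staircase.

    A 5-point circular moving average removes the half-pixel staircase
    of the marching-squares contour so a disc's measured perimeter
    approaches its true circumference (circularity -> 1).
    """
    padded = np.pad(mask.astype(float), 1)
    contours = find_contours(padded, 0.5)
    if not contours:
        return None
    longest = max(contours, key=len) - 1.0
    n = len(longest)
    if n >= 10:
        k = 5
        kernel = np.ones(k) / k
        closed = np.vstack([longest[-(k // 2):], longest,
                            longest[:k // 2]])
        sm = np.column_stack([
            np.convolve(closed[:, 0], kernel, mode="valid"),
            np.convolve(closed[:, 1], kernel, mode="valid")])
        return sm
    return longest


def _polyline_length(pts: np.ndarray, closed: bool = False) -> float:
    d = np.diff(pts, axis=0)
    length = float(np.hypot(d[:, 0], d[:, 1]).sum())
    if closed:
        length += float(np.hypot(*(pts[0] - pts[-1])))
    return length


_REGION_COLUMNS = ["id", "area_um2", "perimeter_um", "major_axis_um",
                   "minor_axis_um", "solidity", "elongation", "circularity",
                   "roughness", "centroid_y", "centroid_x",
                   "mean_intensity", "max_intensity", "sd_intensity"]


def _empty_region_table() -> pd.DataFrame:
    return pd.DataFrame(columns=_REGION_COLUMNS)


def _region_table(labels: np.ndarray, intensity: np.ndarray | None,
                  pixel_size_nm: float) -> pd.DataFrame:
    rows = []
    for rid in np.unique(labels):
        if rid == 0:
            continue
        m = shape_metrics(labels == rid, pixel_size_nm, intensity)
        rows.append({"id": int(rid), **m})
    if not rows:
        return _empty_region_table()
    return pd.DataFrame(rows).reindex(columns=_REGION_COLUMNS)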