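"""Resolution standardisation, background removal, smoothing and masking.

The pipeline standardises every movie so the thinnest tubule spans about
5 pixels (linear upsampling), removes a constant background estimated
from a user-chosen ROI, smooths with an edge-preserving guided filter
(kernel = FWHM_min so tubule edges are not blurred across), and builds a
field mask by multi-level Otsu thresholding followed by a contracted
convex-hull boundary and a fixed erosion, to exclude out-of-focus signal
at the cell margin.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import threshold_multiotsu
from skimage.morphology import convex_hull_image
from skimage.transform import rescale

from .stack import ImageStack


@dataclass
class Mask:
    region: np.ndarray        # bool (H, W): filled interior of the boundary
    boundary: np.ndarray      # bool (H, W), outer contour of the region
    area_um2: float
    #: dark enclosed areas of the thresholded foreground (the polygonal
    #: regions); kept separately so density metrics can use either the
    #: full analysed area (``region``) or structure-occupied pixels only
    holes: np.ndarray | None = None


def upsample_to_min_fwhm(stack: ImageStack, fwhm_min_px: float) -> ImageStack:
    """Linearly upsample so the thinnest tubule spans ~5 px.

    The factor is ``ceil(5 / fwhm_min_px * 2) / 2`` (half-integer steps);
    a measured FWHM_min of 5 px or more leaves the stack untouched.
    Pixel size is divided by the factor.
    """
    if fwhm_min_px <= 0:
        raise ValueError("fwhm_min_px must be > 0")
    f = np.ceil(5.0 / fwhm_min_px * 2.0) / 2.0
    if f <= 1.0:
        return stack
    out = np.stack([
        np.stack([rescale(stack.data[t, c], f, order=1, anti_aliasing=False,
                          preserve_range=True)
                  for c in range(stack.n_channels)])
        for t in range(stack.n_frames)])
    return ImageStack(out, pixel_size_nm=stack.pixel_size_nm / f,
                      frame_interval_s=stack.frame_interval_s,
                      bit_depth=stack.bit_depth)


def subtract_background(stack: ImageStack,
                        roi: tuple[int, int, int, int]) -> ImageStack:
    """Subtract the mean of a rectangular ROI ``(y, x, h, w)`` per channel.

    Output is clamped at zero: later stages assume non-negative
    intensities.
    """
    y, x, h, w = roi
    H, W = stack.shape_yx
    if h <= 0 or w <= 0 or y < 0 or x < 0 or y + h > H or x + w > W:
        raise ValueError(f"ROI {roi} empty or outside the {H}x{W} image")
    out = stack.data.copy()
    for c in range(stack.n_channels):
        bg = out[:, c, y:y + h, x:x + w].mean()
        out[:, c] = np.clip(out[:, c] - bg, 0.0, None)
    return ImageStack(out, pixel_size_nm=stack.pixel_size_nm,
                      frame_interval_s=stack.frame_interval_s,
                      bit_depth=stack.bit_depth)


def guided_filter(frame: np.ndarray, radius_px: int,
                  eps: float | None = None) -> np.ndarray:
    """Edge-preserving guided filter with the image as its own guide.

    Box-filter formulation: within each window the output is the local
    linear model ``a·I + b`` with ``a = var/(var + eps)``, so flat
    regions are averaged while strong edges (var >> eps) pass through.
    ``eps`` defaults to ``(0.01 × intensity range)²``.
    """
    frame = np.asarray(frame, dtype=np.float64)
    if eps is None:
        rng = float(frame.max() - frame.min())
        eps = (0.01 * rng) ** 2 if rng > 0 else 1e-12
    size = 2 * int(radius_px) + 1
    box = lambda a: ndi.uniform_filter(a, size=size, mode="reflect")
    mean = box(frame)
    var = box(frame * frame) - mean * mean
    a = var / (var + eps)
    b = (1.0 - a) * mean
    return box(a) * frame + box(b)


def guided_smooth(stack: ImageStack, kernel_px: int,
                  eps: float | None = None) -> ImageStack:
    """Apply the guided filter to every frame and channel."""
    if kernel_px < 1:
        raise ValueError("kernel_px must be >= 1")
    out = np.empty_like(stack.data)
    for t in range(stack.n_frames):
        for c in range(stack.n_channels):
            out[t, c] = guided_filter(stack.data[t, c], kernel_px, eps)
    out = np.clip(out, 0.0, None)
    return ImageStack(out, pixel_size_nm=stack.pixel_size_nm,
                      frame_interval_s=stack.frame_interval_s,
                      bit_depth=stack.bit_depth)


def build_mask(frame: np.ndarray, pixel_size_nm: float,
               n_partitions: int = 2, shrink: float = 0.7,
               erode_px: int = 5) -> Mask:
    """Analysis mask from the lowest multi-Otsu level plus boundary fitting.

    The histogram is partitioned into ``n_partitions`` classes and the
    lowest threshold keeps all labelled structure (including dim ER
    around very bright inclusions such as fusiform bodies).  Internal
    holes are filled before the boundary is fitted as a contraction of
    the convex hull (``shrink`` = 1 keeps the full hull), the boundary
    is eroded by ``erode_px``, and the holes are then reintroduced.
    """
    if n_partitions not in (2, 3, 4):
        raise ValueError("n_partitions must be 2, 3 or 4")
    if erode_px < 0:
        raise ValueError("erode_px must be >= 0")
    frame = np.asarray(frame, dtype=np.float64)
    if np.ptp(frame) == 0:
        raise ValueError("empty foreground: constant frame has no "
                         "structure to threshold")
    thresholds = threshold_multiotsu(frame, classes=n_partitions)
    fg = frame > thresholds[0]
    if not fg.any():
        raise ValueError(
            "empty foreground after multi-Otsu threshold "
            f"(lowest level {thresholds[0]:.4g}); check background "
            "subtraction and partition count")

    filled = ndi.binary_fill_holes(fg)
    holes = filled & ~fg
    hull = convex_hull_image(filled)
    region = _contract_hull(hull, filled, shrink)
    if erode_px > 0:
        region = ndi.binary_erosion(region, ndi.generate_binary_structure(2, 1),
                                    iterations=erode_px)
    boundary = region & ~ndi.binary_erosion(region)
    holes = holes & region
    area = float(region.sum()) * (pixel_size_nm / 1000.0) ** 2
    return Mask(region=region, boundary=boundary, area_um2=area, holes=holes)


def _contract_hull(hull: np.ndarray, fg: np.ndarray,
                   shrink: float) -> np.ndarray:
    """Contract the convex hull toward the irregular foreground boundary.

    ``shrink`` in [0, 1] interpolates between the convex hull (1) and a
    closing of the foreground itself (0): the hull is intersected with a
    dilation of the filled foreground whose radius scales with
    (1 - shrink) of the maximum hull-to-foreground gap.
    """
    if not (0.0 <= shrink <= 1.0):
        raise ValueError("shrink must be in [0, 1]")
    if shrink >= 1.0:
        return hull
    gap = hull & ~fg
    if not gap.any():
        return hull
    # distance of hull pixels from the foreground
    d = ndi.distance_transform_edt(~fg)
    max_gap = d[gap].max()
    radius = shrink * max_gap
    grow = d <= radius
    return hull & grow
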