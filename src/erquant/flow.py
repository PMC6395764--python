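"""Dense optical flow and per-element motion summaries.

Flow between consecutive frames is estimated with the Farnebäck
method: each frame is approximated locally by quadratic polynomials
(Gaussian-weighted least squares over a small neighbourhood, default
5 px), and the displacement field follows from how the polynomial
coefficients shift between frames, aggregated over a larger averaging
window (default 15 px) and iterated coarse-to-fine over an image
pyramid (default 3 levels) so displacements larger than the
neighbourhood are handled.  The resulting px/frame field is box-averaged
over the averaging window and then converted to µm/s.

Per element (tubule edge, node disc, cisterna region) the summaries
are: scalar mean speed (mean |v|, total movement regardless of
direction), vector mean speed (|mean v|, net directed movement),
maximum speed, and flow coherence = vector mean / scalar mean, which is
1 when all flows move in parallel and 0 for no net movement.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi


@dataclass
class FlowField:
    vy: np.ndarray            # µm/s, (H, W)
    vx: np.ndarray
    pixel_size_nm: float
    frame_interval_s: float
    params: dict = field(default_factory=dict)

    @property
    def speed(self) -> np.ndarray:
        return np.hypot(self.vy, self.vx)


@dataclass
class FlowSummary:
    scalar_mean_um_s: float
    vector_mean_um_s: float
    max_speed_um_s: float
    coherence: float
    mean_divergence_s: float = np.nan
    mean_curl_s: float = np.nan
    direction_mean_deg: float = np.nan
    direction_resultant: float = np.nan
    n_pixels: int = 0


# ---------------------------------------------------------------------------
# Farnebäck polynomial-expansion flow
# ---------------------------------------------------------------------------

def _poly_expand(frame: np.ndarray, n: int, sigma: float):
    """Quadratic expansion f ~ c1 + c2 y + c3 x + c4 y² + c5 x² + c6 yx.

    Separable Gaussian applicability; with unit certainty the normal
    matrix is constant, so the dual basis reduces to fixed 1-D
    correlations (Farnebäck 2002).
    """
    half = n // 2
    x = np.arange(-half, half + 1, dtype=np.float64)
    a = np.exp(-x ** 2 / (2 * sigma ** 2))

    # 1-D correlations with a, a·x, a·x² along each axis
    def corr(img, ky, kx):
        out = ndi.correlate1d(img, ky, axis=0, mode="reflect")
        return ndi.correlate1d(out, kx, axis=1, mode="reflect")

    k0, k1, k2 = a, a * x, a * x ** 2
    m0 = corr(frame, k0, k0)
    my = corr(frame, k1, k0)
    mx = corr(frame, k0, k1)
    myy = corr(frame, k2, k0)
    mxx = corr(frame, k0, k2)
    myx = corr(frame, k1, k1)

    s0 = a.sum()
    s2 = (a * x ** 2).sum()
    s4 = (a * x ** 4).sum()
    # normal equations decouple into (1, y², x²) block + diagonal terms
    A = np.array([[s0 * s0, s2 * s0, s0 * s2],
                  [s2 * s0, s4 * s0, s2 * s2],
                  [s0 * s2, s2 * s2, s0 * s4]])
    Ainv = np.linalg.inv(A)
    b = np.stack([m0, myy, mxx])
    c1, c4, c5 = np.einsum("ij,j...->i...", Ainv, b)
    c2 = my / (s2 * s0)
    c3 = mx / (s0 * s2)
    c6 = myx / (s2 * s2)
    return c1, c2, c3, c4, c5, c6


def _flow_iteration(e1, e2, d0, win: int):
    """One displacement update from two polynomial expansions."""
    _, b1y, b1x, a1yy, a1xx, a1yx = e1
    _, b2y, b2x, a2yy, a2xx, a2yx = e2
    h, w = b1y.shape
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    cy = np.clip(yy + d0[0], 0, h - 1)
    cx = np.clip(xx + d0[1], 0, w - 1)

    def warp(img):
        return ndi.map_coordinates(img, [cy, cx], order=1, mode="nearest")

    Ayy = 0.5 * (a1yy + warp(a2yy))
    Axx = 0.5 * (a1xx + warp(a2xx))
    Ayx = 0.25 * (a1yx + warp(a2yx))     # off-diagonal of A = c6/2
    dby = -0.5 * (warp(b2y) - b1y) + (Ayy * d0[0] + Ayx * d0[1])
    dbx = -0.5 * (warp(b2x) - b1x) + (Ayx * d0[0] + Axx * d0[1])

    # aggregate G = A^T A and h = A^T db over the averaging window
    box = lambda im: ndi.uniform_filter(im, size=win, mode="reflect")
    g11 = box(Ayy * Ayy + Ayx * Ayx)
    g12 = box(Ayy * Ayx + Ayx * Axx)
    g22 = box(Ayx * Ayx + Axx * Axx)
    h1 = box(Ayy * dby + Ayx * dbx)
    h2 = box(Ayx * dby + Axx * dbx)
    det = g11 * g22 - g12 * g12
    det = np.where(np.abs(det) < 1e-12, 1e-12, det)
    dy = (g22 * h1 - g12 * h2) / det
    dx = (g11 * h2 - g12 * h1) / det
    return np.stack([dy, dx])


def farneback_flow(frame_t: np.ndarray, frame_t1: np.ndarray,
                   pixel_size_nm: float, frame_interval_s: float,
                   neighborhood_px: int = 5, pyramid_levels: int = 3,
                   averaging_px: int = 15, iterations: int = 3,
                   poly_sigma: float = 1.1) -> FlowField:
    """Dense Farnebäck flow between two frames, in µm/s."""
    f1 = np.asarray(frame_t, dtype=np.float64)
    f2 = np.asarray(frame_t1, dtype=np.float64)
    if f1.shape != f2.shape:
        raise ValueError("frames must share a shape")
    if f1.ndim != 2:
        raise ValueError("frames must be 2-D; a single frame cannot "
                         "define a flow")

    pyr1, pyr2 = [f1], [f2]
    for _ in range(pyramid_levels - 1):
        if min(pyr1[-1].shape) < 2 * averaging_px:
            break
        pyr1.append(ndi.zoom(ndi.gaussian_filter(pyr1[-1], 1.0), 0.5,
                             order=1))
        pyr2.append(ndi.zoom(ndi.gaussian_filter(pyr2[-1], 1.0), 0.5,
                             order=1))

    d = np.zeros((2, *pyr1[-1].shape))
    for lvl in range(len(pyr1) - 1, -1, -1):
        a, b = pyr1[lvl], pyr2[lvl]
        if d.shape[1:] != a.shape:
            d = np.stack([ndi.zoom(d[0], np.divide(a.shape, d.shape[1:]),
                                   order=1),
                          ndi.zoom(d[1], np.divide(a.shape, d.shape[1:]),
                                   order=1)]) * 2.0
        e1 = _poly_expand(a, neighborhood_px, poly_sigma)
        e2 = _poly_expand(b, neighborhood_px, poly_sigma)
        for _ in range(iterations):
            d = _flow_iteration(e1, e2, d, averaging_px)

    # final box averaging over the 15-px window, then unit conversion
    d = np.stack([ndi.uniform_filter(d[0], averaging_px, mode="reflect"),
                  ndi.uniform_filter(d[1], averaging_px, mode="reflect")])
    scale = pixel_size_nm / 1000.0 / frame_interval_s
    return FlowField(vy=d[0] * scale, vx=d[1] * scale,
                     pixel_size_nm=pixel_size_nm,
                     frame_interval_s=frame_interval_s,
                     params=dict(neighborhood_px=neighborhood_px,
                                 pyramid_levels=pyramid_levels,
                                 averaging_px=averaging_px,
                                 iterations=iterations,
                                 poly_sigma=poly_sigma))


def stack_flow(stack, channel: int = 0, **kwargs) -> list[FlowField]:
    """Flow fields for every consecutive frame pair of an ImageStack."""
    if stack.n_frames < 2:
        raise ValueError("need at least two frames for optical flow")
    return [farneback_flow(stack.frame(t, channel), stack.frame(t + 1,
                                                                channel),
                           stack.pixel_size_nm, stack.frame_interval_s,
                           **kwargs)
            for t in range(stack.n_frames - 1)]


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------

def summarize_flow(flow: FlowField, element_pixels: np.ndarray,
                   with_div_curl: bool = True) -> FlowSummary:
    """Motion summary over an element's pixels (mask or (N, 2) indices)."""
    sel = np.asarray(element_pixels)
    if sel.dtype == bool:
        vy, vx = flow.vy[sel], flow.vx[sel]
    else:
        sel = sel.reshape(-1, 2)
        vy = flow.vy[sel[:, 0], sel[:, 1]]
        vx = flow.vx[sel[:, 0], sel[:, 1]]
    if vy.size == 0:
        raise ValueError("element has no pixels")
    speed = np.hypot(vy, vx)
    scalar = float(speed.mean())
    vector = float(np.hypot(vy.mean(), vx.mean()))
    assert vector <= scalar + 1e-9, "vector mean exceeded scalar mean"
    coh = vector / scalar if scalar > 0 else 0.0
    theta = np.arctan2(vy, vx)
    z = np.exp(1j * theta)[speed > 0]
    if z.size:
        dir_mean = float(np.degrees(np.angle(z.mean())))
        dir_res = float(np.abs(z.mean()))
    else:
        dir_mean, dir_res = np.nan, np.nan
    out = FlowSummary(scalar_mean_um_s=scalar, vector_mean_um_s=vector,
                      max_speed_um_s=float(speed.max()),
                      coherence=float(np.clip(coh, 0.0, 1.0)),
                      direction_mean_deg=dir_mean,
                      direction_resultant=dir_res, n_pixels=int(vy.size))
    if with_div_curl and flow.vy.shape[0] >= 3 and flow.vy.shape[1] >= 3:
        div, curl = divergence_curl(flow)
        if sel.dtype == bool:
            out.mean_divergence_s = float(np.nanmean(div[sel]))
            out.mean_curl_s = float(np.nanmean(curl[sel]))
        else:
            out.mean_divergence_s = float(np.nanmean(div[sel[:, 0],
                                                         sel[:, 1]]))
            out.mean_curl_s = float(np.nanmean(curl[sel[:, 0], sel[:, 1]]))
    return out


def divergence_curl(flow: FlowField) -> tuple[np.ndarray, np.ndarray]:
    """Central-difference divergence and curl of the flow, in s⁻¹.

    div = ∂vx/∂x + ∂vy/∂y; curl = ∂vy/∂x − ∂vx/∂y.  Border pixels
    (one-sided differences) are set to NaN.
    """
    if flow.vy.shape[0] < 3 or flow.vy.shape[1] < 3:
        raise ValueError("field must be at least 3x3")
    h_um = flow.pixel_size_nm / 1000.0
    dvy_dy, dvy_dx = np.gradient(flow.vy, h_um)
    dvx_dy, dvx_dx = np.gradient(flow.vx, h_um)
    div = dvx_dx + dvy_dy
    curl = dvy_dx - dvx_dy
    for arr in (div, curl):
        arr[0, :] = arr[-1, :] = np.nan
        arr[:, 0] = arr[:, -1] = np.nan
    return div, curl


def fit_speed_distribution(speeds: np.ndarray) -> dict:
    """Lognormal fit to per-element speeds.

    Gaussian fit to log speeds; zeros are excluded (their count is
    reported).  ``back_transformed_mean`` is exp(µ), the geometric
    mean on the original scale; the arithmetic lognormal mean
    exp(µ + σ²/2) is also reported.
    """
    speeds = np.asarray(speeds, dtype=np.float64)
    n_zero = int((speeds <= 0).sum())
    pos = speeds[speeds > 0]
    if pos.size < 10:
        raise ValueError("need >= 10 positive speeds for a lognormal fit")
    logs = np.log(pos)
    mu = float(logs.mean())
    sigma = float(logs.std(ddof=1))
    return dict(mu=mu, sigma=sigma,
                back_transformed_mean=float(np.exp(mu)),
                lognormal_mean=float(np.exp(mu + sigma ** 2 / 2.0)),
                n=int(pos.size), n_zero_excluded=n_zero)
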