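"""Synthetic cortical-ER scene generator with full ground truth.

Scenes emulate a paradermal optical section of cortical ER: a polygonal
network of membrane tubules (Voronoi-derived edges) with sub-resolution
radii, flattened sheet-like cisternae filling a fraction of the enclosed
faces, Gaussian psf blur, detector noise, and — in time series — bulk
translation with optional per-frame jitter and immobile anchor points
emulating ER–plasma-membrane contact sites.

Intensity model
---------------
Image intensity is expressed as *thickness-equivalent* fluorophore
signal: a flat sheet of thickness ``T_s`` renders (before blurring) at
the reference intensity ``I_s`` (default 0.35), i.e. the conversion is
``I_s / T_s`` per nm of luminal thickness.  A tubule of radius ``r`` is
deposited as a line mass whose integrated cross-sectional brightness is
``π r² / pixel_size × I_s / T_s`` per pixel of length — proportional to
its cross-sectional area, so the sub-resolution radius is exactly
recoverable from integrated intensity after calibration.  Convolution
with the psf conserves this integral.  The tubule's own cross-sectional
extent (≤ 60 nm radius here) is folded into the psf blur; this leaves
integrated brightness exact and narrows the rendered FWHM by at most a
few percent for the thickest tubes.

Every stochastic operation takes an explicit ``seed``; there is no
global random state.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.spatial import Voronoi
from skimage.draw import line as draw_line, polygon as draw_polygon
from skimage.morphology import skeletonize

from .stack import ImageStack

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass
class SceneTruth:
    """Ground truth for one synthetic scene (per frame where applicable)."""

    skeleton: list            # list of bool (H, W) per frame
    radius_nm: list           # list of float (H, W), NaN off skeleton
    cisterna_mask: list       # list of bool (H, W) per frame
    anchor_px: np.ndarray     # (k, 2) float, (y, x)
    flow_um_s: list | None    # list of (2, H, W) per frame pair, (vy, vx)
    vertices: np.ndarray      # (n, 2) float, (y, x) px — frame 0 geometry
    edges: list               # list of (i, j, radius_nm)
    n_faces: int              # closed polygonal faces of the truth graph
    total_tubule_length_um: float
    scene: dict = field(default_factory=dict)   # render parameters

    @property
    def n_frames(self) -> int:
        return len(self.skeleton)


def _render_frame(shape, vertices, edges, cisterna_polys, *, pixel_size_nm,
                  psf_xy_nm, sheet_ref_intensity, sheet_thickness_nm,
                  anchor_pts=None, anchor_peak=0.0):
    """Render one noise-free frame plus its truth rasters."""
    h, w = shape
    img = np.zeros(shape, dtype=np.float64)
    skel = np.zeros(shape, dtype=bool)
    radius = np.full(shape, np.nan)
    scale = sheet_ref_intensity / sheet_thickness_nm   # intensity per nm

    for poly in cisterna_polys:
        rr, cc = draw_polygon(poly[:, 0], poly[:, 1], shape=shape)
        img[rr, cc] = sheet_ref_intensity

    cist = img > 0

    for i, j, r in edges:
        p0, p1 = vertices[i], vertices[j]
        seg_px = float(np.hypot(*(p1 - p0)))
        if seg_px < 1e-9:
            continue
        n = max(int(np.ceil(seg_px / 0.25)), 1)
        t = (np.arange(n) + 0.5) / n
        pts = p0[None, :] + t[:, None] * (p1 - p0)[None, :]
        mass = (np.pi * r * r / pixel_size_nm) * scale * (seg_px / n)
        _bilinear_deposit(img, pts, mass)
        # truth raster from rounded endpoints (8-connected Bresenham)
        rr, cc = draw_line(*np.round(p0).astype(int), *np.round(p1).astype(int))
        ok = (rr >= 0) & (rr < h) & (cc >= 0) & (cc < w)
        skel[rr[ok], cc[ok]] = True
        radius[rr[ok], cc[ok]] = r

    # enforce the single-pixel-wide invariant at junction clumps
    from .segment import _break_blocks
    thin = _break_blocks(skeletonize(skel, method="zhang"))
    radius[~thin] = np.nan

    sigma_px = psf_xy_nm * _FWHM_TO_SIGMA / pixel_size_nm
    if anchor_pts is not None and len(anchor_pts) and anchor_peak > 0:
        # EPCS-like bright puncta: point mass whose blurred peak is
        # anchor_peak
        mass = anchor_peak * 2.0 * np.pi * sigma_px ** 2
        _bilinear_deposit(img, np.asarray(anchor_pts, float), mass)
    img = gaussian_filter(img, sigma_px, mode="constant")
    return img, thin, radius, cist


def _bilinear_deposit(img, pts, mass):
    h, w = img.shape
    y0 = np.floor(pts[:, 0]).astype(int)
    x0 = np.floor(pts[:, 1]).astype(int)
    fy = pts[:, 0] - y0
    fx = pts[:, 1] - x0
    for dy, dx, wgt in ((0, 0, (1 - fy) * (1 - fx)), (0, 1, (1 - fy) * fx),
                        (1, 0, fy * (1 - fx)), (1, 1, fy * fx)):
        yy, xx = y0 + dy, x0 + dx
        ok = (yy >= 0) & (yy < h) & (xx >= 0) & (xx < w)
        np.add.at(img, (yy[ok], xx[ok]), mass * wgt[ok])


def _apply_noise(img, noise_sd, poisson, rng):
    out = img.copy()
    if poisson:
        # shot noise at a photon budget tied to the signal scale
        photons = 200.0
        out = rng.poisson(np.clip(out, 0, None) * photons) / photons
    if noise_sd > 0:
        out = out + rng.normal(0.0, noise_sd, size=out.shape)
    return np.clip(out, 0.0, None)


def _contract_short_edges(vertices, edges, vkeep, min_edge_px=4.0):
    """Merge vertex pairs joined by sub-resolution edges.

    Iteratively contracts the shortest edge below ``min_edge_px`` to
    its midpoint, then removes self-edges and duplicate straight edges
    (identical endpoints enclose no area).  ``vkeep`` (Voronoi index ->
    vertex index) is remapped onto the surviving vertex set.
    """
    verts = [np.asarray(v, float) for v in vertices]
    parent = list(range(len(verts)))

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    changed = True
    while changed:
        changed = False
        for i, j, _ in edges:
            ri, rj = find(i), find(j)
            if ri == rj:
                continue
            if np.hypot(*(verts[ri] - verts[rj])) < min_edge_px:
                verts[ri] = 0.5 * (verts[ri] + verts[rj])
                parent[rj] = ri
                changed = True

    roots = sorted({find(i) for i in range(len(verts))})
    remap = {r: k for k, r in enumerate(roots)}
    new_vertices = np.asarray([verts[r] for r in roots])
    new_edges = []
    seen = set()
    for i, j, r in edges:
        a, b = remap[find(i)], remap[find(j)]
        if a == b:
            continue
        key = (min(a, b), max(a, b))
        if key in seen:
            continue
        seen.add(key)
        new_edges.append((a, b, r))
    new_vkeep = {k: remap[find(v)] for k, v in vkeep.items()}
    return new_vertices, new_edges, new_vkeep


def generate_network_scene(n_polygons: int = 30,
                           radius_range_nm: tuple[float, float] = (15.0, 60.0),
                           cisterna_fraction: float = 0.1,
                           noise_sd: float = 0.0,
                           poisson_noise: bool = False,
                           psf_xy_nm: float = 140.0,
                           pixel_size_nm: float = 25.0,
                           shape: tuple[int, int] = (256, 256),
                           n_anchors: int = 0,
                           sheet_ref_intensity: float = 0.35,
                           sheet_thickness_nm: float = 40.0,
                           frame_interval_s: float = 0.41,
                           anchor_peak: float = 0.5,
                           seed: int = 0) -> tuple[ImageStack, SceneTruth]:
    """Generate a single-frame synthetic ER network with ground truth.

    ``n_polygons`` seeds a Voronoi tessellation whose finite interior
    ridges become tubules; each tubule gets a radius drawn uniformly
    from ``radius_range_nm``.  ``cisterna_fraction`` of the closed faces
    are filled as uniform sheets.  ``n_anchors`` interior junction
    vertices are marked as immobile anchor points for use by
    :func:`animate_scene`.
    """
    if n_polygons <= 0 and cisterna_fraction <= 0:
        raise ValueError("empty scene: n_polygons == 0 with no cisternae")
    if not (10.0 < radius_range_nm[0] <= radius_range_nm[1] < 200.0):
        raise ValueError("radius_range_nm must lie within (10, 200) nm")
    if not (20.0 <= pixel_size_nm <= 80.0):
        raise ValueError("pixel_size_nm must be in [20, 80] nm")

    rng = np.random.default_rng(seed)
    h, w = shape
    margin = 0.1 * min(h, w)
    pts = np.column_stack([rng.uniform(margin, h - margin, n_polygons),
                           rng.uniform(margin, w - margin, n_polygons)])
    if n_polygons < 4:
        raise ValueError("degenerate scene: n_polygons must be >= 4 to form "
                         "a polygonal network")
    vor = Voronoi(pts)
    box_lo, box_hi = 4.0, None
    inside = lambda v: (box_lo <= v[0] <= h - 1 - box_lo
                        and box_lo <= v[1] <= w - 1 - box_lo)

    vkeep = {}
    vertices = []
    edges = []
    for (i, j), ridge in zip(vor.ridge_vertices, range(len(vor.ridge_vertices))):
        if i == -1 or j == -1:
            continue
        vi, vj = vor.vertices[i], vor.vertices[j]
        if not (inside(vi) and inside(vj)):
            continue
        for k, v in ((i, vi), (j, vj)):
            if k not in vkeep:
                vkeep[k] = len(vertices)
                vertices.append(v)
        r = float(rng.uniform(*radius_range_nm))
        edges.append((vkeep[i], vkeep[j], r))
    if not edges:
        raise ValueError("degenerate scene: no interior tubules generated; "
                         "increase n_polygons or the field size")
    vertices = np.asarray(vertices, dtype=np.float64)
    # contract sub-psf edges (< 4 px ~ below the resolvable scale):
    # two junctions closer than the psf render as one junction anyway,
    # so the geometry is made consistent with what the raster shows
    vertices, edges, vkeep = _contract_short_edges(vertices, edges, vkeep,
                                                   min_edge_px=4.0)

    # enclosed faces by Euler's formula on the exact truth geometry
    import networkx as nx
    tg = nx.Graph()
    tg.add_nodes_from(range(len(vertices)))
    tg.add_edges_from((i, j) for i, j, _ in edges)
    n_faces = (len(edges) - len(vertices)
               + nx.number_connected_components(tg))

    # candidate cisterna faces: regions whose every vertex survived
    face_regions = []
    for k in range(n_polygons):
        region = vor.regions[vor.point_region[k]]
        if not region or -1 in region:
            continue
        if all(ri in vkeep for ri in region):
            face_regions.append([vkeep[ri] for ri in region])

    n_cist = int(np.floor(cisterna_fraction * len(face_regions)))
    cisterna_polys = []
    if n_cist > 0:
        chosen = rng.choice(len(face_regions), size=n_cist, replace=False)
        for ci in chosen:
            poly = vertices[face_regions[ci]]
            centroid = poly.mean(axis=0)
            cisterna_polys.append(centroid + 0.92 * (poly - centroid))

    anchors = np.empty((0, 2))
    if n_anchors > 0:
        deg = np.zeros(len(vertices), int)
        for i, j, _ in edges:
            deg[i] += 1
            deg[j] += 1
        cand = np.flatnonzero(deg >= 3)
        if len(cand) == 0:
            cand = np.arange(len(vertices))
        sel = rng.choice(cand, size=min(n_anchors, len(cand)), replace=False)
        anchors = vertices[sel].copy()

    params = dict(pixel_size_nm=pixel_size_nm, psf_xy_nm=psf_xy_nm,
                  sheet_ref_intensity=sheet_ref_intensity,
                  sheet_thickness_nm=sheet_thickness_nm,
                  noise_sd=noise_sd, poisson_noise=poisson_noise,
                  shape=tuple(shape), frame_interval_s=frame_interval_s,
                  anchor_peak=anchor_peak)
    img, skel, radius, cist = _render_frame(
        shape, vertices, edges, cisterna_polys,
        pixel_size_nm=pixel_size_nm, psf_xy_nm=psf_xy_nm,
        sheet_ref_intensity=sheet_ref_intensity,
        sheet_thickness_nm=sheet_thickness_nm,
        anchor_pts=anchors, anchor_peak=anchor_peak)
    img = _apply_noise(img, noise_sd, poisson_noise, rng)

    length_um = sum(np.hypot(*(vertices[j] - vertices[i]))
                    for i, j, _ in edges) * pixel_size_nm / 1000.0
    truth = SceneTruth(
        skeleton=[skel], radius_nm=[radius], cisterna_mask=[cist],
        anchor_px=anchors, flow_um_s=None, vertices=vertices, edges=edges,
        n_faces=n_faces, total_tubule_length_um=float(length_um),
        scene={**params, "cisterna_polys": cisterna_polys})
    stack = ImageStack(img[None, None], pixel_size_nm=pixel_size_nm,
                       frame_interval_s=frame_interval_s)
    return stack, truth


def generate_straight_tubule(radius_nm: float = 40.0,
                             pixel_size_nm: float = 25.0,
                             psf_xy_nm: float = 140.0,
                             shape: tuple[int, int] = (64, 256),
                             sheet_ref_intensity: float = 0.35,
                             sheet_thickness_nm: float = 40.0,
                             noise_sd: float = 0.0,
                             seed: int = 0) -> tuple[ImageStack, SceneTruth]:
    """One isolated horizontal tubule of known radius — width-test fixture."""
    h, w = shape
    row = h // 2
    vertices = np.array([[row, 8.0], [row, w - 9.0]])
    edges = [(0, 1, float(radius_nm))]
    img, skel, radius, cist = _render_frame(
        shape, vertices, edges, [],
        pixel_size_nm=pixel_size_nm, psf_xy_nm=psf_xy_nm,
        sheet_ref_intensity=sheet_ref_intensity,
        sheet_thickness_nm=sheet_thickness_nm)
    img = _apply_noise(img, noise_sd, False, np.random.default_rng(seed))
    truth = SceneTruth(
        skeleton=[skel], radius_nm=[radius], cisterna_mask=[cist],
        anchor_px=np.empty((0, 2)), flow_um_s=None, vertices=vertices,
        edges=edges, n_faces=0,
        total_tubule_length_um=(w - 17.0) * pixel_size_nm / 1000.0,
        scene=dict(pixel_size_nm=pixel_size_nm, psf_xy_nm=psf_xy_nm,
                   sheet_ref_intensity=sheet_ref_intensity,
                   sheet_thickness_nm=sheet_thickness_nm,
                   noise_sd=noise_sd, poisson_noise=False,
                   shape=tuple(shape), frame_interval_s=0.41,
                   cisterna_polys=[]))
    stack = ImageStack(img[None, None], pixel_size_nm=pixel_size_nm,
                       frame_interval_s=0.41)
    return stack, truth


def animate_scene(truth: SceneTruth, n_frames: int,
                  translation_um_s: tuple[float, float] = (0.0, 0.0),
                  jitter_sd_px: float = 0.0,
                  anchor_px: np.ndarray | None = None,
                  anchor_pin_radius_px: float = 5.0,
                  frame_interval_s: float | None = None,
                  seed: int = 0) -> tuple[ImageStack, SceneTruth]:
    """Animate a generated scene by bulk translation plus rigid jitter.

    Network vertices move with the imposed velocity ``(vy, vx)`` in µm/s;
    vertices within ``anchor_pin_radius_px`` of an anchor stay pinned, so
    their incident tubules stretch, emulating anchored network elements.
    The truth flow field per frame pair equals the imposed displacement
    divided by the frame interval, zeroed within the pin radius of each
    anchor.
    """
    if n_frames < 2:
        raise ValueError("n_frames must be >= 2")
    p = truth.scene["pixel_size_nm"]
    dt = frame_interval_s if frame_interval_s is not None \
        else truth.scene.get("frame_interval_s", 0.41)
    shape = truth.scene["shape"]
    v_px = np.asarray(translation_um_s, float) * 1000.0 / p * dt  # px/frame
    if np.any(np.abs(v_px) > min(shape) / 2):
        raise ValueError("translation exceeds half the field per frame")

    anchors = truth.anchor_px if anchor_px is None else np.asarray(anchor_px,
                                                                   float)
    rng = np.random.default_rng(seed)
    jit = (rng.normal(0.0, jitter_sd_px, size=(n_frames, 2))
           if jitter_sd_px > 0 else np.zeros((n_frames, 2)))
    jit[0] = 0.0
    disp = np.arange(n_frames)[:, None] * v_px[None, :] + jit   # per frame

    wgt = np.ones(len(truth.vertices))
    if len(anchors):
        d = np.linalg.norm(truth.vertices[:, None, :] - anchors[None, :, :],
                           axis=2).min(axis=1)
        wgt[d <= anchor_pin_radius_px] = 0.0

    frames, skels, radii, cists = [], [], [], []
    for k in range(n_frames):
        verts_k = truth.vertices + wgt[:, None] * disp[k][None, :]
        polys_k = [poly + disp[k][None, :]
                   for poly in truth.scene["cisterna_polys"]]
        img, skel, radius, cist = _render_frame(
            shape, verts_k, truth.edges, polys_k,
            pixel_size_nm=p, psf_xy_nm=truth.scene["psf_xy_nm"],
            sheet_ref_intensity=truth.scene["sheet_ref_intensity"],
            sheet_thickness_nm=truth.scene["sheet_thickness_nm"],
            anchor_pts=anchors,
            anchor_peak=truth.scene.get("anchor_peak", 0.0))
        img = _apply_noise(img, truth.scene["noise_sd"],
                           truth.scene["poisson_noise"], rng)
        frames.append(img)
        skels.append(skel)
        radii.append(radius)
        cists.append(cist)

    # truth flow: imposed displacement / frame interval, zero at anchors
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    pin = np.zeros(shape, dtype=bool)
    for ay, ax in anchors:
        pin |= (yy - ay) ** 2 + (xx - ax) ** 2 <= anchor_pin_radius_px ** 2
    flows = []
    for k in range(n_frames - 1):
        step_px = disp[k + 1] - disp[k]
        f = np.empty((2, *shape))
        f[0].fill(step_px[0] * p / 1000.0 / dt)
        f[1].fill(step_px[1] * p / 1000.0 / dt)
        f[:, pin] = 0.0
        flows.append(f)

    out_truth = SceneTruth(
        skeleton=skels, radius_nm=radii, cisterna_mask=cists,
        anchor_px=anchors, flow_um_s=flows, vertices=truth.vertices,
        edges=truth.edges, n_faces=truth.n_faces,
        total_tubule_length_um=truth.total_tubule_length_um,
        scene=dict(truth.scene))
    stack = ImageStack(np.stack(frames)[:, None], pixel_size_nm=p,
                       frame_interval_s=dt)
    return stack, out_truth
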