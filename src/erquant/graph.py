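"""Pixel skeleton to attributed network graph.

Junction pixels (≥ 3 skeleton neighbours, 8-connected) are clustered
into single nodes at their centroid; free ends (1 neighbour) and
isolated pixels become nodes directly.  The chains of degree-2 pixels
between them become edges, each carrying its ordered pixel path and
physical length (sum of 1/√2 steps × pixel size).  Parallel edges and
self-loops are then simplified by inserting degree-2 "resolver" nodes
so every tubule is a distinct simple edge; resolver nodes are excluded
from junction statistics.  Cisternae enter the graph as one node at
their intensity-weighted centroid, linked to every tubule incident on
their boundary by connector edges that count for topology but are
flagged out of tubule statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .segment import CisternaSet, PixelSkeleton
from .width import WidthMap

_NEIGH = [(-1, -1), (-1, 0), (-1, 1), (0, -1),
          (0, 1), (1, -1), (1, 0), (1, 1)]

NODE_COLUMNS = ["node_id", "type", "y", "x", "degree", "strength_nm",
                "mean_branch_angle_deg", "circ_mean_direction_deg",
                "circ_resultant_length", "speed_um_s", "persistency_s"]
EDGE_COLUMNS = ["edge_id", "node_u", "node_v", "length_um",
                "mean_width_nm", "centre_width_nm",
                "centre_width_fallback", "is_cisterna_internal",
                "mean_intensity", "scalar_speed_um_s", "vector_speed_um_s",
                "max_speed_um_s", "coherence", "persistency_s"]


@dataclass
class ERGraph:
    """Attributed multigraph of the ER network for one frame."""

    g: nx.MultiGraph
    pixel_size_nm: float
    frame_index: int = 0
    shape: tuple[int, int] | None = None

    @property
    def n_nodes(self) -> int:
        return self.g.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.g.number_of_edges()

    def junction_nodes(self) -> list:
        return [n for n, d in self.g.nodes(data=True)
                if d.get("type") == "junction"]

    def tubule_edges(self) -> list:
        return [(u, v, k) for u, v, k, d in self.g.edges(keys=True, data=True)
                if not d.get("is_cisterna_internal", False)]

    def nodes_table(self) -> pd.DataFrame:
        rows = []
        for n, d in self.g.nodes(data=True):
            rows.append({
                "node_id": n, "type": d.get("type"),
                "y": d["pos"][0], "x": d["pos"][1],
                "degree": self.g.degree(n),
                "strength_nm": d.get("strength_nm", np.nan),
                "mean_branch_angle_deg": d.get("mean_branch_angle_deg",
                                               np.nan),
                "circ_mean_direction_deg": d.get("circ_mean_direction_deg",
                                                 np.nan),
                "circ_resultant_length": d.get("circ_resultant_length",
                                               np.nan),
                "speed_um_s": d.get("speed_um_s", np.nan),
                "persistency_s": d.get("persistency_s", np.nan),
            })
        return pd.DataFrame(rows, columns=NODE_COLUMNS)

    def edges_table(self) -> pd.DataFrame:
        rows = []
        for u, v, k, d in self.g.edges(keys=True, data=True):
            rows.append({
                "edge_id": d.get("id"), "node_u": u, "node_v": v,
                "length_um": d.get("length_um", np.nan),
                "mean_width_nm": d.get("mean_width_nm", np.nan),
                "centre_width_nm": d.get("centre_width_nm", np.nan),
                "centre_width_fallback": d.get("centre_width_fallback",
                                               False),
                "is_cisterna_internal": d.get("is_cisterna_internal", False),
                "mean_intensity": d.get("mean_intensity", np.nan),
                "scalar_speed_um_s": d.get("scalar_speed_um_s", np.nan),
                "vector_speed_um_s": d.get("vector_speed_um_s", np.nan),
                "max_speed_um_s": d.get("max_speed_um_s", np.nan),
                "coherence": d.get("coherence", np.nan),
                "persistency_s": d.get("persistency_s", np.nan),
            })
        return pd.DataFrame(rows, columns=EDGE_COLUMNS)


def _neighbor_count(skel: np.ndarray) -> np.ndarray:
    k = np.ones((3, 3), dtype=int)
    k[1, 1] = 0
    return ndi.convolve(skel.astype(int), k, mode="constant")


def skeleton_to_graph(skeleton: PixelSkeleton, pixel_size_nm: float,
                      prune_spurs_px: float = 0.0) -> ERGraph:
    """Trace the pixel skeleton into a multigraph of nodes and edges.

    ``prune_spurs_px``: free-end edges shorter than this (in px) are
    removed after tracing — standard skeleton hygiene for psf-scale
    spurs (set to FWHM_min by the pipeline; 0 disables).
    """
    skel = skeleton.pixels
    px_um = pixel_size_nm / 1000.0
    G = nx.MultiGraph()
    if not skel.any():
        return ERGraph(g=G, pixel_size_nm=pixel_size_nm,
                       frame_index=skeleton.frame_index, shape=skel.shape)

    ncount = _neighbor_count(skel)
    node_px = skel & ((ncount >= 3) | (ncount <= 1))
    # cluster adjacent node pixels into single nodes; elongated clusters
    # (a short tubule whose pixels all sit at junction density) are
    # split into two nodes joined by an internal edge so the enclosed
    # faces on either side stay distinct in the graph
    lab, n_clusters = ndi.label(node_px, structure=np.ones((3, 3), int))
    node_of_pixel: dict[tuple[int, int], int] = {}
    next_nid = 1
    eid = 0
    for cid in range(1, n_clusters + 1):
        ys, xs = np.nonzero(lab == cid)
        pts = np.column_stack([ys, xs])
        maxn = ncount[ys, xs].max()
        typ = ("junction" if maxn >= 3
               else "free_end" if maxn == 1 else "punctum")
        d2 = ((pts[:, None, :] - pts[None, :, :]) ** 2).sum(axis=2)
        diam = np.sqrt(d2.max())
        if typ == "junction" and diam > 3.0:
            a, b = np.unravel_index(np.argmax(d2), d2.shape)
            half = (np.sqrt(d2[a]) <= np.sqrt(d2[b]))
            ids = []
            for sel in (half, ~half):
                sub = pts[sel]
                G.add_node(next_nid,
                           pos=tuple(sub.mean(axis=0).astype(float)),
                           type=typ, pixels=sub)
                for y, x in sub:
                    node_of_pixel[(y, x)] = next_nid
                ids.append(next_nid)
                next_nid += 1
            eid += 1
            pa = np.asarray(G.nodes[ids[0]]["pos"])
            pb = np.asarray(G.nodes[ids[1]]["pos"])
            G.add_edge(ids[0], ids[1], id=eid,
                       pixel_path=np.vstack([pts[half], pts[~half]]),
                       length_um=float(np.hypot(*(pa - pb))) * px_um)
        else:
            G.add_node(next_nid,
                       pos=(float(ys.mean()), float(xs.mean())),
                       type=typ, pixels=pts)
            for y, x in zip(ys, xs):
                node_of_pixel[(y, x)] = next_nid
            next_nid += 1

    # chains of path pixels between nodes
    path_px = skel & ~node_px
    visited = np.zeros_like(skel)

    def neighbors(y, x, grid):
        for dy, dx in _NEIGH:
            yy, xx = y + dy, x + dx
            if 0 <= yy < grid.shape[0] and 0 <= xx < grid.shape[1] \
                    and grid[yy, xx]:
                yield yy, xx

    def trace_from(y, x):
        """Walk a chain from one of its tips, return ordered pixels."""
        chain = [(y, x)]
        visited[y, x] = True
        prev = None
        cur = (y, x)
        while True:
            nxts = [p for p in neighbors(*cur, path_px)
                    if not visited[p] and p != prev]
            if not nxts:
                break
            # prefer 4-connected steps so diagonal shortcuts don't skip pixels
            nxts.sort(key=lambda p: abs(p[0] - cur[0]) + abs(p[1] - cur[1]))
            prev = cur
            cur = nxts[0]
            visited[cur] = True
            chain.append(cur)
        return chain

    def attach_nodes(chain):
        ends = []
        for tip, other_tip in ((chain[0], chain[-1]), (chain[-1], chain[0])):
            cands = [node_of_pixel[p] for p in neighbors(*tip, skel)
                     if p in node_of_pixel]
            ends.append(cands)
        return ends

    chain_lab, n_chains = ndi.label(path_px, structure=np.ones((3, 3), int))
    for cid in range(1, n_chains + 1):
        ys, xs = np.nonzero(chain_lab == cid)
        pixels = list(zip(ys.tolist(), xs.tolist()))
        sub = {p: sum(1 for _ in neighbors(*p, path_px)
                      if chain_lab[_[0], _[1]] == cid) for p in pixels}
        tips = [p for p in pixels if sub[p] <= 1]
        start = tips[0] if tips else pixels[0]
        chain = trace_from(*start)
        if len(chain) < len(pixels):
            # branching chain fragment (rare raster ambiguity): restart walks
            for p in pixels:
                if not visited[p]:
                    chain.extend(trace_from(*p))
        ends = attach_nodes(chain)
        u = ends[0][0] if ends[0] else None
        v = None
        if ends[1]:
            # a 1-px chain sees both clusters from both tips: prefer a
            # distinct far node so the edge is not collapsed to a loop
            v = next((c for c in ends[1] if c != u), ends[1][0])
        if u is None and v is None:
            # closed loop with no junction: anchor it at one pixel
            anchor = chain[0]
            u = v = G.number_of_nodes() + 1
            G.add_node(u, pos=(float(anchor[0]), float(anchor[1])),
                       type="junction")
        elif u is None:
            u = v
        elif v is None:
            v = u
        eid += 1
        length = _path_length(chain, G.nodes[u]["pos"], G.nodes[v]["pos"])
        G.add_edge(u, v, id=eid, pixel_path=np.asarray(chain, dtype=int),
                   length_um=length * px_um)

    # directly touching node clusters: one contact edge per pair (kept
    # as a parallel edge when a chain also joins them — the micro-cycle
    # cleanup below decides whether the 2-cycle encloses a real face)
    contact_done: set = set()
    for (y, x), nid in node_of_pixel.items():
        for p in neighbors(y, x, skel):
            other = node_of_pixel.get(p)
            if other is None or other <= nid \
                    or (nid, other) in contact_done:
                continue
            eid += 1
            step = np.hypot(y - p[0], x - p[1])
            G.add_edge(nid, other, id=eid,
                       pixel_path=np.asarray([(y, x), p], dtype=int),
                       length_um=step * px_um)
            contact_done.add((nid, other))

    _drop_micro_cycles(G, min_area_px=4, px_um=px_um)
    if prune_spurs_px > 0:
        _prune_spurs(G, prune_spurs_px * px_um)
    return ERGraph(g=G, pixel_size_nm=pixel_size_nm,
                   frame_index=skeleton.frame_index, shape=skel.shape)


def _drop_micro_cycles(G: nx.MultiGraph, min_area_px: int = 4,
                       px_um: float = 1.0) -> None:
    """Remove raster-artifact cycles that do not enclose a real face.

    At complex junctions the thinning occasionally leaves two nearly
    touching chains (or a tiny self-loop) between the same node pair.
    The enclosed interior of each duplicate cycle is rasterised; if it
    is below ``min_area_px`` (the polygon-segmentation minimum) the
    shorter redundant arm is dropped, keeping graph cycles and
    segmented polygons in one-to-one correspondence.
    """
    def node_pixels(n):
        px = G.nodes[n].get("pixels")
        if px is None:
            y, x = G.nodes[n]["pos"]
            return np.array([[int(round(y)), int(round(x))]])
        return np.asarray(px)

    def enclosed_area(paths, nodes):
        pts = np.vstack([np.asarray(p).reshape(-1, 2) for p in paths]
                        + [node_pixels(n) for n in nodes])
        y0, x0 = pts.min(axis=0) - 1
        y1, x1 = pts.max(axis=0) + 2
        grid = np.zeros((y1 - y0, x1 - x0), dtype=bool)
        grid[pts[:, 0] - y0, pts[:, 1] - x0] = True
        filled = ndi.binary_fill_holes(grid)
        return int((filled & ~grid).sum())

    # tiny self-loops
    for u, v, k, d in list(G.edges(keys=True, data=True)):
        if u == v and enclosed_area([d["pixel_path"]], [u]) < min_area_px:
            G.remove_edge(u, v, key=k)
    # duplicate arms enclosing no real face
    by_pair: dict = {}
    for u, v, k, d in G.edges(keys=True, data=True):
        if u == v:
            continue
        by_pair.setdefault((min(u, v), max(u, v)), []).append(
            (d["length_um"], u, v, k, d["pixel_path"]))
    for (u, v), arms in by_pair.items():
        if len(arms) < 2:
            continue
        arms.sort(key=lambda a: a[0])
        keep = arms[-1]
        for arm in arms[:-1]:
            area = enclosed_area([arm[4], keep[4]], [u, v])
            if area < min_area_px:
                G.remove_edge(arm[1], arm[2], key=arm[3])


def _path_length(chain, pos_u, pos_v) -> float:
    pts = np.asarray(chain, dtype=float)
    if len(pts) > 1:
        d = np.diff(pts, axis=0)
        length = np.hypot(d[:, 0], d[:, 1]).sum()
    else:
        length = 0.0
    length += np.hypot(*(pts[0] - np.asarray(pos_u)))
    length += np.hypot(*(pts[-1] - np.asarray(pos_v)))
    return float(length)


def _prune_spurs(G: nx.MultiGraph, min_len_um: float) -> None:
    changed = True
    while changed:
        changed = False
        for n in [n for n in G.nodes
                  if G.degree(n) == 1 and G.nodes[n]["type"] == "free_end"]:
            if n not in G or G.degree(n) != 1:
                continue
            (u, v, k) = next(iter(G.edges(n, keys=True)))
            if G.edges[u, v, k]["length_um"] < min_len_um:
                G.remove_node(n)
                changed = True


def resolve_duplicates(graph: ERGraph) -> ERGraph:
    """Split parallel edges and self-loops with degree-2 resolver nodes."""
    G = graph.g
    next_node = max(G.nodes, default=0) + 1
    next_eid = max((d.get("id", 0) for *_, d in G.edges(data=True)),
                   default=0) + 1

    def split(u, v, k):
        nonlocal next_node, next_eid
        d = G.edges[u, v, k]
        path = d["pixel_path"]
        mid = len(path) // 2
        pos = tuple(map(float, path[mid] if len(path) else
                        np.mean([G.nodes[u]["pos"], G.nodes[v]["pos"]],
                                axis=0)))
        G.remove_edge(u, v, key=k)
        r = next_node
        next_node += 1
        G.add_node(r, pos=pos, type="resolver")
        half = d["length_um"] / 2.0
        extra = {key: val for key, val in d.items()
                 if key not in ("id", "pixel_path", "length_um")}
        G.add_edge(u, r, id=next_eid, pixel_path=path[:mid + 1],
                   length_um=half, **extra)
        G.add_edge(r, v, id=next_eid + 1, pixel_path=path[mid:],
                   length_um=half, **extra)
        next_eid += 2

    for _ in range(4):        # self-loop split leaves a parallel pair once
        dupes = []
        seen = set()
        for u, v, k in G.edges(keys=True):
            key = (min(u, v), max(u, v))
            if u == v:
                dupes.append((u, v, k))
            elif key in seen:
                dupes.append((u, v, k))
            else:
                seen.add(key)
        if not dupes:
            break
        # split one arm of each duplicate pair / each loop
        done_pairs = set()
        for u, v, k in dupes:
            key = (min(u, v), max(u, v))
            if key in done_pairs or not G.has_edge(u, v, k):
                continue
            split(u, v, k)
            done_pairs.add(key)
    return graph


def centre_weighted_width(graph: ERGraph, u, v, k,
                          widthmap: WidthMap) -> tuple[float, bool]:
    """Mean calibrated width over the edge interior.

    Pixels within an exclusion distance of each endpoint node are
    dropped; the distance is the maximum initial (unweighted) width of
    the tubules meeting that node, converted to pixels.  Short spurs
    that fall entirely inside the exclusion zones fall back to the
    unweighted mean and are flagged.
    """
    G = graph.g
    d = G.edges[u, v, k]
    path = d["pixel_path"]
    wmap = 2.0 * widthmap.calibrated_radius_nm    # width = 2 r
    vals = wmap[path[:, 0], path[:, 1]]

    def initial_width(node):
        ws = []
        for a, b, kk in G.edges(node, keys=True):
            p = G.edges[a, b, kk]["pixel_path"]
            w = np.nanmean(wmap[p[:, 0], p[:, 1]])
            if np.isfinite(w):
                ws.append(w)
        return max(ws) if ws else 0.0

    keep = np.ones(len(path), dtype=bool)
    for node in (u, v):
        excl_px = initial_width(node) / graph.pixel_size_nm
        pos = np.asarray(G.nodes[node]["pos"])
        dist = np.hypot(path[:, 0] - pos[0], path[:, 1] - pos[1])
        keep &= dist > excl_px
    kept = vals[keep]
    if np.isfinite(kept).any():
        return float(np.nanmean(kept)), False
    return float(np.nanmean(vals)) if np.isfinite(vals).any() else np.nan, \
        True


def _arclength_midpoint(path: np.ndarray) -> np.ndarray:
    """Sub-pixel point at half the arclength of a pixel path."""
    pts = np.asarray(path, dtype=float)
    if len(pts) == 1:
        return pts[0]
    steps = np.hypot(*np.diff(pts, axis=0).T)
    arclen = np.concatenate([[0.0], np.cumsum(steps)])
    half = arclen[-1] / 2.0
    i = int(np.searchsorted(arclen, half))
    i = min(max(i, 1), len(pts) - 1)
    seg = arclen[i] - arclen[i - 1]
    f = (half - arclen[i - 1]) / seg if seg > 0 else 0.0
    return pts[i - 1] + f * (pts[i] - pts[i - 1])


def node_properties(graph: ERGraph, node) -> dict:
    """Branch angles, circular summary and strength for one node."""
    G = graph.g
    pos = np.asarray(G.nodes[node]["pos"], dtype=float)
    dirs = []
    strength = 0.0
    for u, v, k in G.edges(node, keys=True):
        d = G.edges[u, v, k]
        path = d["pixel_path"]
        if len(path) == 0:
            continue
        vec = _arclength_midpoint(path) - pos
        if np.hypot(*vec) < 1e-9:
            other = v if u == node else u
            vec = np.asarray(G.nodes[other]["pos"], float) - pos
        dirs.append(np.arctan2(vec[0], vec[1]))   # angle in image plane
        cw = d.get("centre_width_nm", np.nan)
        if np.isfinite(cw):
            strength += cw
    out = {"strength_nm": strength}
    if len(dirs) >= 2:
        ang = np.sort(np.mod(dirs, 2 * np.pi))
        gaps = np.diff(np.concatenate([ang, [ang[0] + 2 * np.pi]]))
        out["branch_angles_deg"] = np.degrees(gaps)
        out["mean_branch_angle_deg"] = float(np.degrees(gaps).mean())
    else:
        out["branch_angles_deg"] = np.empty(0)
        out["mean_branch_angle_deg"] = np.nan
    if dirs:
        z = np.exp(1j * np.asarray(dirs))
        out["circ_mean_direction_deg"] = float(np.degrees(np.angle(z.mean())))
        out["circ_resultant_length"] = float(np.abs(z.mean()))
    else:
        out["circ_mean_direction_deg"] = np.nan
        out["circ_resultant_length"] = np.nan
    return out


def annotate_graph(graph: ERGraph, widthmap: WidthMap,
                   frame: np.ndarray | None = None) -> ERGraph:
    """Fill per-edge width/intensity and per-node property vectors."""
    G = graph.g
    wmap = 2.0 * widthmap.calibrated_radius_nm
    for u, v, k in G.edges(keys=True):
        d = G.edges[u, v, k]
        path = d["pixel_path"]
        vals = wmap[path[:, 0], path[:, 1]]
        d["mean_width_nm"] = float(np.nanmean(vals)) \
            if np.isfinite(vals).any() else np.nan
        cw, fb = centre_weighted_width(graph, u, v, k, widthmap)
        d["centre_width_nm"] = cw
        d["centre_width_fallback"] = fb
        if frame is not None:
            d["mean_intensity"] = float(frame[path[:, 0], path[:, 1]].mean())
    for n in G.nodes:
        G.nodes[n].update(node_properties(graph, n))
    return graph


def attach_cisternae(graph: ERGraph, cisternae: CisternaSet,
                     frame: np.ndarray | None = None,
                     boundary_halo_px: int = 2) -> ERGraph:
    """Add one node per cisterna, wired to tubules on its boundary."""
    if cisternae is None or len(cisternae) == 0:
        return graph
    G = graph.g
    next_node = max(G.nodes, default=0) + 1
    next_eid = max((d.get("id", 0) for *_, d in G.edges(data=True)),
                   default=0) + 1
    widths = [d.get("centre_width_nm", np.nan)
              for *_, d in G.edges(data=True)]
    mean_cw = float(np.nanmean(widths)) if np.isfinite(widths).any() \
        else np.nan
    px_um = graph.pixel_size_nm / 1000.0

    labels = cisternae.labels
    for _, row in cisternae.table.iterrows():
        rid = int(row["id"])
        region = labels == rid
        if frame is not None and np.asarray(frame)[region].sum() > 0:
            wts = np.asarray(frame) * region
            cy, cx = ndi.center_of_mass(wts)
        else:
            cy, cx = ndi.center_of_mass(region)
        cnode = next_node
        next_node += 1
        G.add_node(cnode, pos=(float(cy), float(cx)), type="cisterna",
                   cisterna_id=rid, area_um2=float(row["area_um2"]))
        halo = ndi.binary_dilation(region, iterations=boundary_halo_px)
        for n, nd in list(G.nodes(data=True)):
            if nd.get("type") in ("cisterna",):
                continue
            y, x = nd["pos"]
            iy, ix = int(round(y)), int(round(x))
            if 0 <= iy < halo.shape[0] and 0 <= ix < halo.shape[1] \
                    and halo[iy, ix] and n != cnode:
                G.add_edge(cnode, n, id=next_eid,
                           pixel_path=np.asarray([(int(round(cy)),
                                                   int(round(cx))),
                                                  (iy, ix)], dtype=int),
                           length_um=float(np.hypot(cy - y, cx - x)) * px_um,
                           centre_width_nm=mean_cw, mean_width_nm=mean_cw,
                           is_cisterna_internal=True)
                next_eid += 1
    return graph


def add_puncta(graph: ERGraph, puncta: np.ndarray,
               snap_radius_px: float) -> ERGraph:
    """Snap punctum centroids to a nearby node, else insert new nodes."""
    G = graph.g
    next_node = max(G.nodes, default=0) + 1
    positions = {n: np.asarray(d["pos"]) for n, d in G.nodes(data=True)}
    for py, px_ in np.asarray(puncta).reshape(-1, 2):
        best, bestd = None, np.inf
        for n, p in positions.items():
            dd = np.hypot(p[0] - py, p[1] - px_)
            if dd < bestd:
                best, bestd = n, dd
        if best is not None and bestd <= snap_radius_px:
            G.nodes[best]["type"] = "punctum"
        else:
            G.add_node(next_node, pos=(float(py), float(px_)),
                       type="punctum")
            next_node += 1
    return graph
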