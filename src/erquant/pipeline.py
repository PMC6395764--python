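"""Full per-movie analysis pipeline and batch orchestration.

``analyze_movie`` runs, in order: resolution standardisation,
background subtraction, guided smoothing, masking, per-frame tubule /
cisterna / polygon segmentation, width estimation, graph conversion,
tubule morphology profiles, cisternal texture, optical flow and
persistency, and assembles one summary metric row per movie for group
statistics.  Single-frame stacks are legal: dynamics and persistency
are skipped with a logged notice and their metrics reported NaN.

``batch`` maps the per-movie analysis over a file/stack list, attaches
group labels and, with two or more groups, runs the MANOVA/ANOVA
comparison.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import AnalysisConfig
from .stack import ImageStack, read_stack
from . import preprocess as pp
from .segment import (CisternaSet, PixelSkeleton, PolygonSet,
                      hysteresis_skeleton, phase_congruency_ft,
                      segment_cisternae, segment_polygons)
from .width import WidthMap, estimate_widths
from .graph import (ERGraph, add_puncta, annotate_graph, attach_cisternae,
                    resolve_duplicates, skeleton_to_graph)
from .profiles import extract_trace, find_peaks_troughs
from .texture import aggregate_textures, texture_table
from .flow import FlowSummary, stack_flow, summarize_flow
from .persistency import (element_persistency, persistent_nodes,
                          structure_persistency)

log = logging.getLogger("erquant")


@dataclass
class FrameResult:
    skeleton: PixelSkeleton
    mask: pp.Mask
    cisternae: CisternaSet
    polygons: PolygonSet
    widths: WidthMap
    graph: ERGraph


@dataclass
class MovieResult:
    stack: ImageStack                    # preprocessed stack
    config: AnalysisConfig
    frames: list[FrameResult]
    flow_fields: list = field(default_factory=list)
    flow_edges: pd.DataFrame | None = None
    texture: pd.DataFrame | None = None
    texture_pooled: dict | None = None
    profile_events: pd.DataFrame | None = None
    persistency_map: object | None = None
    persistent_node_table: pd.DataFrame | None = None
    manifest: dict = field(default_factory=dict)

    def summary_row(self) -> dict:
        """One metric row for the movie (means across frames/elements)."""
        row: dict = {}
        edge_tabs = [f.graph.edges_table() for f in self.frames]
        et = pd.concat(edge_tabs, ignore_index=True) if edge_tabs \
            else pd.DataFrame()
        if len(et):
            tub = et[~et["is_cisterna_internal"]]

            def nmean(col, agg=np.nanmean):
                vals = tub[col].to_numpy(dtype=float)
                return float(agg(vals)) if np.isfinite(vals).any() \
                    else np.nan

            row["tubule_length_um"] = nmean("length_um")
            row["tubule_width_nm"] = nmean("centre_width_nm")
            row["tubule_mean_speed_um_s"] = nmean("scalar_speed_um_s")
            row["tubule_max_speed_um_s"] = nmean("max_speed_um_s",
                                                 np.nanmax)
            row["tubule_coherence"] = nmean("coherence")
            row["tubule_persistency_s"] = nmean("persistency_s")
        cis_tabs = [f.cisternae.table for f in self.frames]
        ct = pd.concat(cis_tabs, ignore_index=True) if cis_tabs \
            else pd.DataFrame()
        for col, name in (("area_um2", "cisterna_area_um2"),
                          ("perimeter_um", "cisterna_perimeter_um"),
                          ("circularity", "cisterna_circularity")):
            row[name] = float(np.nanmean(ct[col])) if len(ct) else np.nan
        poly_tabs = [f.polygons.table for f in self.frames]
        pt = pd.concat(poly_tabs, ignore_index=True) if poly_tabs \
            else pd.DataFrame()
        for col, name in (("area_um2", "polygon_area_um2"),
                          ("perimeter_um", "polygon_perimeter_um"),
                          ("circularity", "polygon_circularity")):
            row[name] = float(np.nanmean(pt[col])) if len(pt) else np.nan
        if self.texture is not None and len(self.texture):
            for col in ("contrast_norm", "correlation", "energy",
                        "homogeneity"):
                row[f"cisterna_{col}"] = float(
                    np.nanmean(self.texture[col]))
        else:
            for col in ("contrast_norm", "correlation", "energy",
                        "homogeneity"):
                row[f"cisterna_{col}"] = np.nan
        return row


def preprocess_stack(stack: ImageStack, config: AnalysisConfig,
                     measured_fwhm_min_px: float | None = None
                     ) -> ImageStack:
    """Upsample, background-subtract and smooth a stack."""
    fwhm = measured_fwhm_min_px if measured_fwhm_min_px is not None \
        else config.fwhm_min_px
    out = pp.upsample_to_min_fwhm(stack, fwhm)
    if config.bg_roi is not None:
        out = pp.subtract_background(out, config.bg_roi)
    out = pp.guided_smooth(out, max(int(round(config.fwhm_min_px / 2)), 1))
    return out


def analyze_frame(stack: ImageStack, t: int,
                  config: AnalysisConfig) -> FrameResult:
    ch = config.analysis_channel
    frame = stack.frame(t, ch)
    mask = pp.build_mask(frame, stack.pixel_size_nm,
                         n_partitions=config.mask_partitions,
                         shrink=config.boundary_shrink,
                         erode_px=config.boundary_erode_px)
    ft = phase_congruency_ft(frame, n_scales=config.n_scales,
                             n_orients=config.n_orients,
                             noise_k=config.noise_k)
    skel = hysteresis_skeleton(ft, lo=config.hysteresis_lo,
                               hi=config.hysteresis_hi,
                               hmin=config.hmin_depth, frame_index=t)
    skel = PixelSkeleton(skel.pixels & mask.region, frame_index=t)
    cist = segment_cisternae(frame, skel, config.fwhm_max_px,
                             config.min_cisterna_area_um2,
                             stack.pixel_size_nm)
    # skeleton pixels inside cisternae are flagged out of tubule stats
    tub_skel = PixelSkeleton(skel.pixels & (cist.labels == 0),
                             frame_index=t)
    polys = segment_polygons(skel, cist, mask, stack.pixel_size_nm)
    widths = estimate_widths(frame, tub_skel, config.calibration,
                             stack.pixel_size_nm,
                             max_radius_px=max(int(round(
                                 config.fwhm_max_px)), 3),
                             cisternae=cist)
    graph = skeleton_to_graph(
        tub_skel, stack.pixel_size_nm,
        prune_spurs_px=config.fwhm_min_px if config.prune_spurs else 0.0)
    graph = resolve_duplicates(graph)
    graph = annotate_graph(graph, widths, frame)
    graph = attach_cisternae(graph, cist, frame)
    if len(cist.puncta):
        graph = add_puncta(graph, cist.puncta, config.fwhm_min_px)
    return FrameResult(skeleton=skel, mask=mask, cisternae=cist,
                       polygons=polys, widths=widths, graph=graph)


def analyze_movie(stack: ImageStack, config: AnalysisConfig,
                  preprocessed: bool = False) -> MovieResult:
    """Run the full analysis on one (t, c, y, x) stack."""
    work = stack if preprocessed else preprocess_stack(stack, config)
    frames = [analyze_frame(work, t, config) for t in range(work.n_frames)]
    result = MovieResult(stack=work, config=config, frames=frames)
    result.manifest = {"n_frames": work.n_frames,
                       "pixel_size_nm": work.pixel_size_nm,
                       "frame_interval_s": work.frame_interval_s,
                       "warnings": []}

    _add_texture(result)
    _add_profiles(result)
    if work.n_frames >= 2:
        _add_dynamics(result)
        _add_persistency(result)
    else:
        msg = "single frame: dynamics and persistency skipped"
        log.info(msg)
        result.manifest["warnings"].append(msg)
    return result


def _add_texture(result: MovieResult) -> None:
    cfg = result.config
    dist = max(int(round(cfg.fwhm_min_px / 2)), 1)   # minimum tubule radius
    tabs = []
    for t, fr in enumerate(result.frames):
        tab = texture_table(fr.cisternae,
                            result.stack.frame(t, cfg.analysis_channel),
                            distance_px=dist, n_bins=cfg.glcm_bins)
        tab["frame"] = t
        tabs.append(tab)
    result.texture = pd.concat(tabs, ignore_index=True) if tabs else None
    for t, fr in enumerate(result.frames):
        if len(fr.cisternae):
            m = aggregate_textures(fr.cisternae,
                                   result.stack.frame(
                                       t, cfg.analysis_channel),
                                   distance_px=dist, n_bins=cfg.glcm_bins,
                                   mode="pooled")
            result.texture_pooled = dict(contrast=m.contrast,
                                         correlation=m.correlation,
                                         energy=m.energy,
                                         homogeneity=m.homogeneity)
            break


def _add_profiles(result: MovieResult) -> None:
    cfg = result.config
    events = []
    for t, fr in enumerate(result.frames):
        frames_c = [result.stack.frame(t, c)
                    for c in range(result.stack.n_channels)]
        for u, v, k in fr.graph.tubule_edges():
            d = fr.graph.g.edges[u, v, k]
            if len(d.get("pixel_path", ())) < 5:
                continue
            try:
                trace = extract_trace(
                    fr.graph, u, v, k, frames_c,
                    normal_halfwidth_px=cfg.fwhm_max_px / 2.0,
                    node_exclude_px=cfg.fwhm_min_px / 2.0,
                    width_map=2.0 * fr.widths.calibrated_radius_nm)
                ps = find_peaks_troughs(trace, cfg.peak_height_frac,
                                        cfg.peak_prominence_frac)
            except ValueError:
                continue
            if not len(ps.events):
                continue
            ev = ps.events.copy()
            ev["frame"] = t
            ev["edge_id"] = d.get("id")
            events.append(ev)
    result.profile_events = (pd.concat(events, ignore_index=True)
                             if events else pd.DataFrame(
        columns=["kind", "channel", "index", "height", "prominence",
                 "position_um", "width_nm", "frame", "edge_id"]))


def _add_dynamics(result: MovieResult) -> None:
    cfg = result.config
    ffs = stack_flow(result.stack, channel=cfg.analysis_channel,
                     neighborhood_px=cfg.flow_neighborhood_px,
                     pyramid_levels=cfg.flow_pyramid_levels,
                     averaging_px=cfg.flow_averaging_px)
    result.flow_fields = ffs
    rows = []
    for t, fr in enumerate(result.frames[:-1]):
        ff = ffs[t]
        for u, v, k in fr.graph.g.edges(keys=True):
            d = fr.graph.g.edges[u, v, k]
            path = d["pixel_path"]
            try:
                s = summarize_flow(ff, path, with_div_curl=False)
            except ValueError:
                continue
            d["scalar_speed_um_s"] = s.scalar_mean_um_s
            d["vector_speed_um_s"] = s.vector_mean_um_s
            d["max_speed_um_s"] = s.max_speed_um_s
            d["coherence"] = s.coherence
            rows.append({"frame": t, "edge_id": d.get("id"),
                         "scalar_mean": s.scalar_mean_um_s,
                         "vector_mean": s.vector_mean_um_s,
                         "max_speed": s.max_speed_um_s,
                         "coherence": s.coherence})
        for n, nd in fr.graph.g.nodes(data=True):
            y, x = (int(round(p)) for p in nd["pos"])
            rad = max(int(round(cfg.fwhm_min_px)), 1)
            yy, xx = np.mgrid[max(y - rad, 0):y + rad + 1,
                              max(x - rad, 0):x + rad + 1]
            ok = (yy < ff.vy.shape[0]) & (xx < ff.vy.shape[1]) \
                & ((yy - y) ** 2 + (xx - x) ** 2 <= rad ** 2)
            if ok.any():
                s = summarize_flow(ff, np.column_stack(
                    [yy[ok], xx[ok]]), with_div_curl=False)
                nd["speed_um_s"] = s.scalar_mean_um_s
    result.flow_edges = pd.DataFrame(rows)


def _add_persistency(result: MovieResult) -> None:
    cfg = result.config
    skels = [fr.skeleton.pixels for fr in result.frames]
    cists = [fr.cisternae.labels > 0 for fr in result.frames]
    pmap = structure_persistency(
        skels, cists, result.stack.frame_interval_s,
        dilate_px=max(int(round(cfg.fwhm_min_px / 2)), 1), mode="sum")
    result.persistency_map = pmap
    for fr in result.frames:
        for u, v, k in fr.graph.g.edges(keys=True):
            d = fr.graph.g.edges[u, v, k]
            d["persistency_s"] = element_persistency(
                pmap, d["pixel_path"], "tubule")
        for n, nd in fr.graph.g.nodes(data=True):
            y, x = (int(round(p)) for p in nd["pos"])
            if 0 <= y < pmap.tubule_s.shape[0] \
                    and 0 <= x < pmap.tubule_s.shape[1]:
                nd["persistency_s"] = float(pmap.tubule_s[y, x])
    if result.stack.n_frames >= 3:
        result.persistent_node_table = persistent_nodes(
            result.stack, sigma_px=cfg.fwhm_min_px / 2.0,
            threshold=cfg.node_maxima_threshold,
            channel=cfg.analysis_channel)


# ---------------------------------------------------------------------------
# output
# ---------------------------------------------------------------------------

def write_results(result: MovieResult, out_dir) -> list[str]:
    """Write tables (CSV), graph (GraphML), overlays (TIFF), config (JSON).

    Deterministic: identical inputs produce byte-identical CSVs.
    """
    import networkx as nx
    import tifffile

    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
        probe = out / ".write_probe"
        probe.write_text("")
        probe.unlink()
    except OSError as exc:
        raise ValueError(f"output directory {out} not writable") from exc

    written: list[str] = []

    def save_csv(df: pd.DataFrame, name: str) -> None:
        path = out / name
        df.to_csv(path, index=False, float_format="%.6g", encoding="utf-8")
        written.append(name)

    from .graph import EDGE_COLUMNS, NODE_COLUMNS
    from .segment import _REGION_COLUMNS

    def stack_tables(tables, columns):
        tables = [t for t in tables if len(t)]
        if not tables:
            return pd.DataFrame(columns=columns + ["frame"])
        return pd.concat(tables, ignore_index=True)

    edges = stack_tables([fr.graph.edges_table().assign(frame=t)
                          for t, fr in enumerate(result.frames)],
                         EDGE_COLUMNS)
    nodes = stack_tables([fr.graph.nodes_table().assign(frame=t)
                          for t, fr in enumerate(result.frames)],
                         NODE_COLUMNS)
    cis = stack_tables([fr.cisternae.table.assign(frame=t)
                        for t, fr in enumerate(result.frames)],
                       _REGION_COLUMNS)
    pol = stack_tables([fr.polygons.table.assign(frame=t)
                        for t, fr in enumerate(result.frames)],
                       _REGION_COLUMNS)
    save_csv(edges, "edges.csv")
    save_csv(nodes, "nodes.csv")
    save_csv(cis, "cisternae.csv")
    save_csv(pol, "polygons.csv")
    if result.texture is not None:
        save_csv(result.texture, "texture.csv")
    if result.profile_events is not None:
        save_csv(result.profile_events, "profile_events.csv")
    if result.flow_edges is not None:
        save_csv(result.flow_edges, "flow_edges.csv")
    if result.persistent_node_table is not None:
        save_csv(result.persistent_node_table, "persistent_nodes.csv")

    if result.frames:
        g0 = result.frames[0].graph
        nx.write_graphml(_graphml_safe(g0.g), out / "graph_frame0.graphml")
        written.append("graph_frame0.graphml")
        skel = np.stack([fr.skeleton.pixels for fr in result.frames])
        tifffile.imwrite(out / "skeleton.tif",
                         (skel * 255).astype(np.uint8))
        written.append("skeleton.tif")
        labels = np.stack([fr.cisternae.labels for fr in result.frames])
        tifffile.imwrite(out / "cisterna_labels.tif",
                         labels.astype(np.uint16))
        written.append("cisterna_labels.tif")

    result.config.to_json(out / "config.json")
    written.append("config.json")
    manifest = dict(result.manifest)
    manifest["files"] = sorted(written + ["manifest.json"])
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    written.append("manifest.json")
    return written


def _graphml_safe(g):
    """Copy with array attributes flattened to GraphML-safe scalars."""
    import networkx as nx
    out = nx.MultiGraph()
    for n, d in g.nodes(data=True):
        dd = {}
        for key, val in d.items():
            if key == "pos":
                dd["y"], dd["x"] = float(val[0]), float(val[1])
            elif isinstance(val, np.ndarray):
                continue
            elif isinstance(val, (np.floating, np.integer)):
                dd[key] = val.item()
            else:
                dd[key] = val
        out.add_node(n, **dd)
    for u, v, k, d in g.edges(keys=True, data=True):
        dd = {}
        for key, val in d.items():
            if isinstance(val, np.ndarray):
                continue
            elif isinstance(val, (np.floating, np.integer)):
                dd[key] = val.item()
            else:
                dd[key] = val
        out.add_edge(u, v, key=k, **dd)
    return out


# ---------------------------------------------------------------------------
# batch
# ---------------------------------------------------------------------------

def batch(movies: dict[str, "ImageStack | str"], config: AnalysisConfig,
          group_map: dict[str, str], control_label: str | None = None):
    """Analyse a set of movies and compare groups.

    ``movies`` maps movie id to an ImageStack or a TIFF path;
    ``group_map`` maps every movie id to its group label.  Returns
    ``(MetricTable, GroupComparison | None, failures)``; per-movie
    failures are logged and skipped, not fatal.
    """
    from .evalstats import MetricTable, compare_groups

    missing = [mid for mid in movies if mid not in group_map]
    if missing:
        raise ValueError(f"group_map missing movie ids: {missing}")
    rows, ids, groups, failures = [], [], [], {}
    for mid, mv in movies.items():
        try:
            stack = mv if isinstance(mv, ImageStack) \
                else read_stack(mv, config)
            res = analyze_movie(stack, config)
            rows.append(res.summary_row())
            ids.append(mid)
            groups.append(group_map[mid])
        except Exception as exc:       # noqa: BLE001 — batch robustness
            log.warning("movie %s failed: %s", mid, exc)
            failures[mid] = str(exc)
    if not rows:
        raise ValueError("no movie analysed successfully")
    table = MetricTable(pd.DataFrame(rows, index=ids),
                        pd.Series(groups, index=ids))
    comparison = None
    if len(set(groups)) >= 2 and control_label is not None:
        data = table.data.dropna(axis=1)
        comparison = compare_groups(
            MetricTable(data, table.group), control_label)
    return table, comparison, failures
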