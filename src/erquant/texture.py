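"""Grey-level co-occurrence texture metrics for cisternal sub-structure.

The GLCM is the joint probability p(i, j) of intensity-bin pairs at a
fixed pixel offset, accumulated over four directions (NW, N, NE, E)
plus their symmetric counterparts so the result is orientation
independent.  Intensities are binned into a fixed number of equal bins
(default 32) over a fixed intensity range shared across a study, so
metrics are comparable between treatments.  The offset distance is set
to the minimum tubule radius to maximise sensitivity to appressed
sub-resolution tubules inside apparent sheets.

Metrics (sums over all bin pairs):

* contrast      Σ |i−j|² p(i,j), normalised by (n_bins−1)² to [0, 1]
* correlation   Σ (i−μ_i)(j−μ_j) p(i,j) / (σ_i σ_j), in [−1, 1]
* energy        Σ p(i,j)², in (0, 1]
* homogeneity   Σ p(i,j) / (1 + |i−j|), in (0, 1]

A perfectly uniform region puts all mass in one diagonal cell: contrast
is exactly 0 and homogeneity exactly 1 there, while energy evaluates to
1 by its formula (all mass in one cell) and correlation is undefined
(σ = 0) and flagged NaN.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .segment import CisternaSet

_OFFSETS = {"NW": (-1, -1), "N": (-1, 0), "NE": (-1, 1), "E": (0, 1)}


@dataclass
class GLCM:
    p: np.ndarray             # (n_bins, n_bins) joint probability
    n_bins: int
    offset_distance_px: int
    n_pairs: int
    symmetric: bool = True


@dataclass
class TextureMetrics:
    contrast: float           # normalised by (n_bins - 1)^2
    correlation: float
    energy: float
    homogeneity: float
    n_pairs: int = 0


def build_glcm(region: np.ndarray, frame: np.ndarray, distance_px: int = 1,
               n_bins: int = 32,
               intensity_range: tuple[float, float] | None = None) -> GLCM:
    """Symmetric GLCM over a labelled region.

    Pairs with either member outside the region are dropped (no
    padding), keeping the statistic region-pure.  ``intensity_range``
    fixes the binning range; default is (0, frame max), but a study
    should pass the full bit-depth range once for comparability.
    """
    region = np.asarray(region, bool)
    frame = np.asarray(frame, float)
    if region.sum() < 2:
        raise ValueError("region must have >= 2 pixels")
    if intensity_range is None:
        intensity_range = (0.0, float(frame.max()) or 1.0)
    lo, hi = intensity_range
    binned = np.clip(((frame - lo) / (hi - lo) * n_bins).astype(int),
                     0, n_bins - 1)

    acc = np.zeros((n_bins, n_bins), dtype=np.int64)
    h, w = region.shape
    d = int(distance_px)
    for dy, dx in _OFFSETS.values():
        dy, dx = dy * d, dx * d
        ys0 = slice(max(0, -dy), min(h, h - dy))
        xs0 = slice(max(0, -dx), min(w, w - dx))
        ys1 = slice(max(0, dy), min(h, h + dy))
        xs1 = slice(max(0, dx), min(w, w + dx))
        ok = region[ys0, xs0] & region[ys1, xs1]
        a = binned[ys0, xs0][ok]
        b = binned[ys1, xs1][ok]
        np.add.at(acc, (a, b), 1)
        np.add.at(acc, (b, a), 1)      # symmetric counterpart
    n_pairs = int(acc.sum())
    if n_pairs == 0:
        raise ValueError("no valid pixel pairs at distance "
                         f"{distance_px} inside the region")
    return GLCM(p=acc / n_pairs, n_bins=n_bins, offset_distance_px=d,
                n_pairs=n_pairs)


def glcm_metrics(glcm: GLCM) -> TextureMetrics:
    """The four texture statistics from a normalised GLCM."""
    p = glcm.p
    n = glcm.n_bins
    i = np.arange(n)[:, None]
    j = np.arange(n)[None, :]
    contrast = float((np.abs(i - j) ** 2 * p).sum()) / (n - 1) ** 2
    energy = float((p ** 2).sum())
    homogeneity = float((p / (1.0 + np.abs(i - j))).sum())
    mu_i = float((i * p).sum())
    mu_j = float((j * p).sum())
    var_i = float(((i - mu_i) ** 2 * p).sum())
    var_j = float(((j - mu_j) ** 2 * p).sum())
    if var_i <= 0 or var_j <= 0:
        correlation = np.nan
    else:
        correlation = float(((i - mu_i) * (j - mu_j) * p).sum()
                            / np.sqrt(var_i * var_j))
    return TextureMetrics(contrast=contrast, correlation=correlation,
                          energy=energy, homogeneity=homogeneity,
                          n_pairs=glcm.n_pairs)


def aggregate_textures(cisternae: CisternaSet, frame: np.ndarray,
                       distance_px: int = 1, n_bins: int = 32,
                       intensity_range: tuple[float, float] | None = None,
                       mode: str = "per_cisterna_mean") -> TextureMetrics:
    """Texture metrics across all cisternae of a frame.

    ``per_cisterna_mean`` averages the metrics computed per cisterna;
    ``pooled`` accumulates one GLCM over all cisternae, which weights
    each cisterna by its pixel-pair count.
    """
    if len(cisternae) == 0:
        raise ValueError("no cisternae to aggregate")
    if mode not in ("per_cisterna_mean", "pooled"):
        raise ValueError(f"unknown mode {mode!r}")
    labels = cisternae.labels
    ids = np.unique(labels)
    ids = ids[ids > 0]
    if intensity_range is None:
        intensity_range = (0.0, float(np.asarray(frame).max()) or 1.0)

    glcms = [build_glcm(labels == rid, frame, distance_px, n_bins,
                        intensity_range) for rid in ids]
    if mode == "pooled":
        counts = sum(g.p * g.n_pairs for g in glcms)
        total = sum(g.n_pairs for g in glcms)
        pooled = GLCM(p=counts / total, n_bins=n_bins,
                      offset_distance_px=int(distance_px), n_pairs=int(total))
        return glcm_metrics(pooled)
    ms = [glcm_metrics(g) for g in glcms]
    return TextureMetrics(
        contrast=float(np.mean([m.contrast for m in ms])),
        correlation=float(np.nanmean([m.correlation for m in ms]))
        if any(np.isfinite(m.correlation) for m in ms) else np.nan,
        energy=float(np.mean([m.energy for m in ms])),
        homogeneity=float(np.mean([m.homogeneity for m in ms])),
        n_pairs=int(sum(m.n_pairs for m in ms)))


def texture_table(cisternae: CisternaSet, frame: np.ndarray,
                  distance_px: int = 1, n_bins: int = 32,
                  intensity_range: tuple[float, float] | None = None):
    """Per-cisterna texture metrics as DataFrame columns."""
    import pandas as pd
    rows = []
    labels = cisternae.labels
    for rid in np.unique(labels):
        if rid == 0:
            continue
        try:
            m = glcm_metrics(build_glcm(labels == rid, frame, distance_px,
                                        n_bins, intensity_range))
            rows.append({"id": int(rid), "contrast_norm": m.contrast,
                         "correlation": m.correlation, "energy": m.energy,
                         "homogeneity": m.homogeneity,
                         "n_pairs": m.n_pairs})
        except ValueError:
            rows.append({"id": int(rid), "contrast_norm": np.nan,
                         "correlation": np.nan, "energy": np.nan,
                         "homogeneity": np.nan, "n_pairs": 0})
    return pd.DataFrame(rows, columns=["id", "contrast_norm", "correlation",
                                       "energy", "homogeneity", "n_pairs"])
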