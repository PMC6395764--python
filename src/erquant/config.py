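"""Acquisition and analysis parameters.

All spatial thresholds that depend on the microscope are keyed on two
user-measured scale parameters: ``fwhm_min_px``, the full-width
half-maximum of the thinnest tubule in pixels, and ``fwhm_max_px``, the
FWHM across the widest three-way junction.  Sub-resolution width
calibration additionally needs the lateral point-spread-function extent
``psf_xy_nm`` and a reference sheet thickness ``sheet_thickness_nm``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
import json


@dataclass
class PsfCalibration:
    """Constants relating fluorescence intensity to ER volume.

    The model assumes the luminal marker is uniformly distributed, that
    intensity is linear in the amount of marker, and that tubules and
    sheets are fully contained within a stylised cylindrical psf of
    lateral extent ``psf_xy_nm``.  A sheet of thickness
    ``sheet_thickness_nm`` imaged under this psf yields the reference
    intensity ``sheet_ref_intensity`` (as a fraction of the image
    maximum), against which tubule intensities are scaled.
    """

    psf_xy_nm: float = 140.0
    sheet_thickness_nm: float = 40.0
    sheet_ref_intensity: float = 0.35
    #: mean cortical ER width from serial block-face SEM reconstructions,
    #: for context when judging calibrated radii
    em_reference_width_nm: float = 40.51

    def __post_init__(self) -> None:
        if self.psf_xy_nm <= 0 or self.sheet_thickness_nm <= 0:
            raise ValueError("psf_xy_nm and sheet_thickness_nm must be > 0")
        if not self.sheet_ref_intensity > 0:
            raise ValueError("sheet_ref_intensity must be > 0")


@dataclass
class AnalysisConfig:
    """All tunable analysis parameters with their customary defaults."""

    fwhm_min_px: float = 5.0
    fwhm_max_px: float = 15.0
    psf_xy_nm: float = 140.0
    sheet_thickness_nm: float = 40.0
    sheet_ref_intensity: float = 0.35
    # tubule segmentation
    hysteresis_lo: float = 0.3
    hysteresis_hi: float = 0.5
    hmin_depth: float = 0.05
    n_scales: int = 4
    n_orients: int = 6
    noise_k: float = 2.0
    # cisternae / polygons
    min_cisterna_area_um2: float = 0.3
    boundary_shrink: float = 0.7
    boundary_erode_px: int = 5
    mask_partitions: int = 2
    # tubule morphology profiles
    peak_height_frac: float = 0.05
    peak_prominence_frac: float = 0.03
    # dynamics / persistency
    persistency_lag_frames: int = 12
    node_maxima_threshold: float = 0.4
    flow_neighborhood_px: int = 5
    flow_pyramid_levels: int = 3
    flow_averaging_px: int = 15
    # texture
    glcm_bins: int = 32
    # orchestration
    analysis_channel: int = 0
    bg_roi: tuple | None = None        # (y, x, h, w) background ROI
    prune_spurs: bool = True

    def __post_init__(self) -> None:
        if not self.hysteresis_lo < self.hysteresis_hi:
            raise ValueError("hysteresis_lo must be < hysteresis_hi")
        if self.fwhm_min_px < 3:
            raise ValueError("fwhm_min_px must be >= 3 (upsample first)")
        if self.sheet_ref_intensity <= 0:
            raise ValueError("sheet_ref_intensity must be > 0")
        for name in ("hysteresis_lo", "hysteresis_hi", "hmin_depth",
                     "boundary_shrink", "peak_height_frac",
                     "peak_prominence_frac", "node_maxima_threshold"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name} must be in [0, 1], got {v}")

    @property
    def calibration(self) -> PsfCalibration:
        return PsfCalibration(
            psf_xy_nm=self.psf_xy_nm,
            sheet_thickness_nm=self.sheet_thickness_nm,
            sheet_ref_intensity=self.sheet_ref_intensity,
        )

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "AnalysisConfig":
        with open(path, encoding="utf-8") as fh:
            raw = json.load(fh)
        if raw.get("bg_roi") is not None:
            raw["bg_roi"] = tuple(raw["bg_roi"])
        return cls(**raw)
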