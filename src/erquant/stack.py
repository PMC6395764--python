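"""Calibrated image stacks and TIFF input.

The canonical in-memory container is :class:`ImageStack`: a
``(t, channel, y, x)`` float array with physical pixel size (nm) and
frame interval (s).  Readers permute whatever layout the file declares
into this axis order.  Coordinates are 0-based ``(row, col) = (y, x)``
with the origin at the top-left; physical positions in µm are obtained
by multiplying by ``pixel_size_nm / 1000``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import tifffile

from .config import AnalysisConfig


@dataclass
class ImageStack:
    data: np.ndarray          # (t, c, y, x), non-negative float
    pixel_size_nm: float
    frame_interval_s: float = 0.41
    bit_depth: int = 8

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 4:
            raise ValueError(f"data must be (t, c, y, x), got {self.data.shape}")
        if self.data.min() < 0:
            raise ValueError("intensities must be non-negative")
        if self.pixel_size_nm <= 0:
            raise ValueError("pixel_size_nm must be > 0")
        if self.n_frames > 1 and self.frame_interval_s <= 0:
            raise ValueError("frame_interval_s must be > 0 for time series")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def shape_yx(self) -> tuple[int, int]:
        return self.data.shape[2], self.data.shape[3]

    @property
    def pixel_size_um(self) -> float:
        return self.pixel_size_nm / 1000.0

    def frame(self, t: int, channel: int = 0) -> np.ndarray:
        return self.data[t, channel]


def read_stack(path, config: AnalysisConfig | None = None, *,
               n_frames: int | None = None, n_channels: int = 1,
               pixel_size_nm: float | None = None,
               frame_interval_s: float | None = None) -> ImageStack:
    """Read a single- or multi-page grayscale TIFF / OME-TIFF.

    Pixel size and frame interval are taken from OME metadata when
    present, else from the explicit arguments.  A multi-page file is
    interpreted as ``n_frames`` × ``n_channels`` pages (time-major);
    with neither given, all pages are frames of a single channel.
    """
    with tifffile.TiffFile(path) as tif:
        arr = tif.asarray()
        if arr.dtype.kind == "f" or (arr.ndim == 3 and arr.shape[-1] in (3, 4)
                                     and tif.pages[0].photometric == 2):
            raise ValueError(
                "only 8/16-bit grayscale TIFFs are supported; "
                "got RGB or float data without an explicit mapping")
        ome_px, ome_dt = _ome_metadata(tif)

    px = ome_px if ome_px is not None else pixel_size_nm
    if px is None:
        raise ValueError("pixel size missing: not in file metadata and not "
                         "given explicitly")
    dt = ome_dt or frame_interval_s or 0.41

    if arr.ndim == 2:
        arr = arr[None, None]
    elif arr.ndim == 3:
        pages = arr.shape[0]
        if n_frames is None:
            n_frames = pages // n_channels
        if n_frames * n_channels != pages:
            raise ValueError(
                f"{pages} pages cannot be split into "
                f"{n_frames} frames x {n_channels} channels")
        arr = arr.reshape(n_frames, n_channels, *arr.shape[1:])
    elif arr.ndim != 4:
        raise ValueError(f"cannot interpret TIFF of shape {arr.shape}")

    bit_depth = 16 if arr.dtype.itemsize > 1 else 8
    return ImageStack(arr.astype(np.float64), pixel_size_nm=float(px),
                      frame_interval_s=float(dt), bit_depth=bit_depth)


def _ome_metadata(tif) -> tuple[float | None, float | None]:
    """Extract (pixel_size_nm, frame_interval_s) from OME-XML if present."""
    if not tif.is_ome:
        return None, None
    import re
    xml = tif.ome_metadata or ""
    px = None
    m = re.search(r'PhysicalSizeX="([\d.eE+-]+)"', xml)
    if m:
        px = float(m.group(1))
        unit = re.search(r'PhysicalSizeXUnit="([^"]+)"', xml)
        u = unit.group(1) if unit else "µm"
        px *= {"nm": 1.0, "µm": 1000.0, "um": 1000.0}.get(u, 1000.0)
    dt = None
    m = re.search(r'TimeIncrement="([\d.eE+-]+)"', xml)
    if m:
        dt = float(m.group(1))
    return px, dt


def write_stack(path, stack: ImageStack) -> None:
    """Write an ImageStack as a multi-page TIFF (pages = t x c, time-major)."""
    scale = 65535 if stack.bit_depth == 16 else 255
    top = stack.data.max()
    data = stack.data / top * scale if top > 0 else stack.data
    dtype = np.uint16 if stack.bit_depth == 16 else np.uint8
    pages = data.reshape(-1, *stack.shape_yx).astype(dtype)
    tifffile.imwrite(path, pages)
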