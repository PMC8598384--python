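"""Image, ROI and settings I/O.

Root scans arrive as 8- or 16-bit greyscale (or colour) rasters from flatbed
scanners, usually with a bright background and dark roots.  Everything
downstream works on an 8-bit intensity raster plus an optional spatial
resolution in pixels per millimetre; this module normalises inputs to that
representation and handles the two sidecar text formats (rectangular ROI
annotations and `key,value` settings CSV files).
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from PIL import Image

__all__ = [
    "GreyImage",
    "RegionOfInterest",
    "AnalysisConfig",
    "load_image",
    "resolution_to_px_per_mm",
    "read_roi_file",
    "write_roi_file",
    "read_config",
    "write_config",
]

MM_PER_INCH = 25.4

ROI_HEADER = "#rootquant-roi v1"


@dataclass
class GreyImage:
    """A 2-D greyscale raster with optional physical resolution.

    ``pixels`` holds intensities in [0, 255] (uint8).  ``px_per_mm`` is the
    scan resolution; when absent all features are reported in pixel units.
    """

    pixels: np.ndarray
    px_per_mm: Optional[float] = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise ValueError("GreyImage requires a non-empty 2-D array")
        if self.px_per_mm is not None and not self.px_per_mm > 0:
            raise ValueError("px_per_mm must be positive")

    @property
    def height_px(self) -> int:
        return self.pixels.shape[0]

    @property
    def width_px(self) -> int:
        return self.pixels.shape[1]

    def crop(self, roi: "RegionOfInterest") -> "GreyImage":
        """Sub-image under ``roi``, clipped to the image bounds."""
        r = roi.clipped(self.height_px, self.width_px)
        if r is None:
            raise ValueError(f"ROI {roi.name!r} lies entirely outside the image")
        return GreyImage(
            self.pixels[r.y : r.y + r.height, r.x : r.x + r.width],
            px_per_mm=self.px_per_mm,
        )


@dataclass(frozen=True)
class RegionOfInterest:
    """Axis-aligned rectangle, 0-based, origin top-left, y downward."""

    name: str
    x: int
    y: int
    width: int
    height: int

    def __post_init__(self) -> None:
        if self.width < 1 or self.height < 1:
            raise ValueError(f"ROI {self.name!r}: width and height must be >= 1")

    def clipped(self, img_h: int, img_w: int) -> Optional["RegionOfInterest"]:
        """Intersection with the image rectangle, or None if empty."""
        x0, y0 = max(self.x, 0), max(self.y, 0)
        x1 = min(self.x + self.width, img_w)
        y1 = min(self.y + self.height, img_h)
        if x1 <= x0 or y1 <= y0:
            return None
        return RegionOfInterest(self.name, x0, y0, x1 - x0, y1 - y0)


@dataclass
class AnalysisConfig:
    """Analysis options controlling the whole pipeline.

    ``mode`` selects the trait set: ``broken_roots`` for disconnected washed
    fragments, ``whole_root`` for a connected crown (adds extent, convex-hull,
    hole and angle traits).  Areas for the background filter and hole filling
    are in mm^2 when a resolution is set, else px^2.
    """

    mode: str = "broken_roots"
    threshold_level: int = 128
    invert: bool = False
    filter_background: bool = False
    max_component_size: float = 8.0
    fill_holes: bool = False
    max_hole_size: float = 8.0
    edge_smoothing: bool = False
    rdp_tolerance_px: float = 2.0
    pruning_enabled: bool = True
    pruning_threshold_px: int = 5
    diameter_bin_edges: tuple = ()
    dpi: Optional[float] = None
    px_per_mm: Optional[float] = None

    def __post_init__(self) -> None:
        if self.mode not in ("broken_roots", "whole_root"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if not 0 <= int(self.threshold_level) <= 255:
            raise ValueError("threshold_level must be in [0, 255]")
        if self.rdp_tolerance_px < 0:
            raise ValueError("rdp_tolerance_px must be >= 0")
        if self.pruning_threshold_px < 0:
            raise ValueError("pruning_threshold_px must be >= 0")
        edges = tuple(float(e) for e in self.diameter_bin_edges)
        if any(b <= a for a, b in zip(edges, edges[1:])) or any(e < 0 for e in edges):
            raise ValueError("diameter_bin_edges must be non-negative, strictly ascending")
        self.diameter_bin_edges = edges
        if self.dpi is not None and self.px_per_mm is not None:
            raise ValueError("give dpi or px_per_mm, not both")

    def resolved_px_per_mm(self) -> Optional[float]:
        """Pixels per mm from whichever resolution spec is present."""
        if self.dpi is not None:
            return resolution_to_px_per_mm(dpi=self.dpi)
        if self.px_per_mm is not None:
            return resolution_to_px_per_mm(px_per_mm=self.px_per_mm)
        return None


def resolution_to_px_per_mm(dpi: Optional[float] = None,
                            px_per_mm: Optional[float] = None) -> float:
    """Convert a resolution spec (DPI or px/mm) to pixels per millimetre."""
    if (dpi is None) == (px_per_mm is None):
        raise ValueError("exactly one of dpi / px_per_mm must be given")
    value = dpi if dpi is not None else px_per_mm
    if not value > 0:
        raise ValueError("resolution must be positive")
    return value / MM_PER_INCH if dpi is not None else float(value)


def load_image(path) -> GreyImage:
    """Read a PNG/JPEG/BMP/TIFF raster as an 8-bit greyscale image.

    Colour inputs are reduced to their red channel; 16-bit inputs are scaled
    full-scale to full-scale (divide by 257).  Embedded DPI metadata, when
    present, populates ``px_per_mm``.
    """
    path = Path(path)
    try:
        with Image.open(path) as im:
            dpi = im.info.get("dpi")
            arr = np.asarray(im)
    except (OSError, Image.UnidentifiedImageError) as exc:
        raise IOError(f"cannot read image file {path}: {exc}") from exc
    if arr.ndim == 3:  # colour: keep the red channel only
        arr = arr[..., 0]
    if arr.size == 0 or arr.ndim != 2:
        raise ValueError(f"{path}: zero-sized or non-2D image")
    if arr.dtype == np.uint16:
        arr = (arr // 257).astype(np.uint8)
    elif arr.dtype == np.int32 and arr.max() > 255:  # PIL mode "I" 16-bit PNGs
        arr = (np.clip(arr, 0, 65535) // 257).astype(np.uint8)
    elif arr.dtype == bool:
        arr = arr.astype(np.uint8) * 255
    else:
        arr = np.clip(arr, 0, 255).astype(np.uint8)
    px_per_mm = None
    if dpi:
        d = float(dpi[0] if isinstance(dpi, (tuple, list)) else dpi)
        if d > 0:
            px_per_mm = d / MM_PER_INCH
    return GreyImage(arr, px_per_mm=px_per_mm)


def read_roi_file(path) -> list:
    """Parse an ROI annotation file: one ``name,x,y,width,height`` per line."""
    rois = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = [p.strip() for p in line.split(",")]
            if len(parts) != 5:
                raise ValueError(f"{path}:{lineno}: expected 'name,x,y,width,height'")
            name = parts[0]
            try:
                x, y, w, h = (int(p) for p in parts[1:])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer ROI geometry") from exc
            rois.append(RegionOfInterest(name, x, y, w, h))
    return rois


def write_roi_file(rois: Sequence[RegionOfInterest], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(ROI_HEADER + "\n")
        for r in rois:
            fh.write(f"{r.name},{r.x},{r.y},{r.width},{r.height}\n")


# settings CSV: key -> (parser, serialiser)
def _parse_bool(s: str) -> bool:
    s = s.strip().lower()
    if s in ("true", "1", "yes"):
        return True
    if s in ("false", "0", "no"):
        return False
    raise ValueError(f"not a boolean: {s!r}")


def _parse_edges(s: str):
    s = s.strip()
    return () if not s else tuple(float(p) for p in s.split(";"))


def _fmt_edges(edges) -> str:
    return ";".join(repr(float(e)) for e in edges)


def _parse_opt_float(s: str):
    return None if not s.strip() else float(s)


_CONFIG_FIELDS = {
    "mode": (str, str),
    "threshold_level": (int, str),
    "invert": (_parse_bool, str),
    "filter_background": (_parse_bool, str),
    "max_component_size": (float, repr),
    "fill_holes": (_parse_bool, str),
    "max_hole_size": (float, repr),
    "edge_smoothing": (_parse_bool, str),
    "rdp_tolerance_px": (float, repr),
    "pruning_enabled": (_parse_bool, str),
    "pruning_threshold_px": (int, str),
    "diameter_bin_edges": (_parse_edges, _fmt_edges),
    "dpi": (_parse_opt_float, lambda v: "" if v is None else repr(float(v))),
    "px_per_mm": (_parse_opt_float, lambda v: "" if v is None else repr(float(v))),
}


def read_config(path) -> AnalysisConfig:
    """Read an AnalysisConfig from a ``key,value`` CSV.

    Unknown keys warn and are ignored; missing keys take the defaults.
    """
    values = {}
    with open(path, "r", encoding="utf-8", newline="") as fh:
        for row in csv.reader(fh):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            key = row[0].strip()
            if key.startswith("#"):
                continue
            raw = row[1].strip() if len(row) > 1 else ""
            if key not in _CONFIG_FIELDS:
                warnings.warn(f"{path}: ignoring unknown settings key {key!r}")
                continue
            parser, _ = _CONFIG_FIELDS[key]
            try:
                values[key] = parser(raw)
            except ValueError as exc:
                raise ValueError(f"{path}: bad value for {key!r}: {raw!r}") from exc
    return AnalysisConfig(**values)


def write_config(config: AnalysisConfig, path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh)
        for key, (_, fmt) in _CONFIG_FIELDS.items():
            w.writerow([key, fmt(getattr(config, key))])
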