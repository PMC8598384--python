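"""Synthetic scan scenes with analytic ground truth.

Emulates flatbed scans of copper wires and simple branched roots: dark
elongated strokes on a bright background, with controlled rendered pixel
width, length, orientation and optional speckle/hole corruption.  Ground
truth is computed from the *rendered* integer stroke width and the rendered
cap extent, so pipeline tests measure algorithm error rather than
rasterization error.

The default wire gauge set is the American Wire Gauge series 40, 32, 28, 22,
16 and 10 (0.08-2.59 mm diameter) scanned at 600 DPI, the combination used
for physical wire validation of scanner-based root measurement.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .image_io import GreyImage, MM_PER_INCH

__all__ = [
    "AWG_DIAMETERS_MM",
    "WireSpec",
    "SceneTruth",
    "render_wires",
    "render_branched_root",
    "corrupt",
    "sample_wire_scene",
]

# AWG gauge -> nominal diameter (mm)
AWG_DIAMETERS_MM = {
    40: 0.0799,
    32: 0.2019,
    28: 0.3211,
    22: 0.6438,
    16: 1.291,
    10: 2.588,
}

DEFAULT_PX_PER_MM = 600.0 / MM_PER_INCH  # 600 DPI scans

BACKGROUND_LEVEL = 230
WIRE_LEVEL = 60


@dataclass(frozen=True)
class WireSpec:
    """One wire: physical diameter and length, placement and shape.

    ``position`` is the (row, col) of the centreline start in pixels;
    ``orientation_deg`` is measured clockwise from horizontal (0 = East,
    90 = South).  ``shape`` is ``straight`` or ``arc``; arcs bulge gently
    with the given sagitta-to-length ratio.
    """

    diameter_mm: float
    length_mm: float
    position: Tuple[float, float] = (0.0, 0.0)
    orientation_deg: float = 0.0
    shape: str = "straight"
    arc_sagitta_frac: float = 0.08

    def rendered_width_px(self, px_per_mm: float) -> int:
        return max(1, int(round(self.diameter_mm * px_per_mm)))


@dataclass
class SceneTruth:
    """Analytic ground truth for a rendered scene (cylinder model).

    The average diameter is length-weighted, total surface area is
    sum(pi * D_i * L_i) and volume sum(pi * (D_i/2)^2 * L_i); all additive
    over wires.
    """

    total_length_mm: float = 0.0
    weighted_avg_diameter_mm: float = 0.0
    surface_area_mm2: float = 0.0
    volume_mm3: float = 0.0
    object_count: int = 0


def _cap_extension_px(width_px: int, stroke_radius: float) -> int:
    """How far the rendered round cap extends beyond the centreline end."""
    off = 0.0 if width_px % 2 == 1 else 0.5
    return int(math.floor(math.sqrt(max(stroke_radius ** 2 - off ** 2, 0.0))))


def _stroke_radius(width_px: int) -> float:
    return (width_px - 1) / 2.0 + 0.25


def _paint_segment(canvas: np.ndarray, p0, p1, radius: float) -> np.ndarray:
    """Pixels within ``radius`` of segment p0-p1 (pixel-centre metric)."""
    h, w = canvas.shape
    r0 = max(int(math.floor(min(p0[0], p1[0]) - radius - 1)), 0)
    r1 = min(int(math.ceil(max(p0[0], p1[0]) + radius + 1)), h - 1)
    c0 = max(int(math.floor(min(p0[1], p1[1]) - radius - 1)), 0)
    c1 = min(int(math.ceil(max(p0[1], p1[1]) + radius + 1)), w - 1)
    rr, cc = np.mgrid[r0:r1 + 1, c0:c1 + 1]
    d = np.array(p1) - np.array(p0)
    L2 = float(d @ d)
    vr, vc = rr - p0[0], cc - p0[1]
    if L2 == 0:
        dist2 = vr ** 2 + vc ** 2
    else:
        t = np.clip((vr * d[0] + vc * d[1]) / L2, 0.0, 1.0)
        dist2 = (vr - t * d[0]) ** 2 + (vc - t * d[1]) ** 2
    out = np.zeros_like(canvas, dtype=bool)
    out[r0:r1 + 1, c0:c1 + 1] = dist2 <= radius ** 2
    return out


def _paint_arc(canvas: np.ndarray, centre, arc_radius: float,
               theta0: float, theta1: float, radius: float) -> np.ndarray:
    """Pixels within ``radius`` of a circular arc (angles in radians)."""
    h, w = canvas.shape
    ext = arc_radius + radius + 2
    r0 = max(int(centre[0] - ext), 0)
    r1 = min(int(centre[0] + ext), h - 1)
    c0 = max(int(centre[1] - ext), 0)
    c1 = min(int(centre[1] + ext), w - 1)
    rr, cc = np.mgrid[r0:r1 + 1, c0:c1 + 1]
    vr, vc = rr - centre[0], cc - centre[1]
    ang = np.arctan2(vr, vc)
    lo, hi = min(theta0, theta1), max(theta0, theta1)
    inside = (ang >= lo) & (ang <= hi)
    dist = np.abs(np.hypot(vr, vc) - arc_radius)
    # endpoints give the caps
    for th in (theta0, theta1):
        er = centre[0] + arc_radius * math.sin(th)
        ec = centre[1] + arc_radius * math.cos(th)
        dist_end = np.hypot(rr - er, cc - ec)
        end_hit = dist_end <= radius
        inside |= end_hit
        dist = np.where(end_hit & ~((ang >= lo) & (ang <= hi)), dist_end, dist)
    out = np.zeros_like(canvas, dtype=bool)
    out[r0:r1 + 1, c0:c1 + 1] = inside & (dist <= radius)
    return out


def render_wires(specs: Sequence[WireSpec], px_per_mm: float = DEFAULT_PX_PER_MM,
                 canvas_shape: Optional[Tuple[int, int]] = None,
                 background_level: int = BACKGROUND_LEVEL,
                 wire_level: int = WIRE_LEVEL) -> Tuple[GreyImage, SceneTruth]:
    """Render wires on a bright canvas and return the image with its truth.

    Wires must not overlap and must fit the canvas; violations raise.  For
    axis-aligned straight wires the rendered cross-section is exactly the
    rounded integer width (the centreline is lattice-aligned for odd widths
    and placed between pixel rows for even widths).

    Ground truth models each wire as a cylinder over its *centreline*: length
    is the centreline length, surface and volume use the rendered integer
    width.  The rendered round caps extend a little beyond the centreline;
    their skeleton spurs are what root pruning removes, so the measured
    medial axis also ends at the centreline ends.
    """
    if canvas_shape is None:
        canvas_shape = _auto_canvas(specs, px_per_mm)
    canvas = np.zeros(canvas_shape, dtype=bool)
    lengths, diams = [], []
    for spec in specs:
        w = spec.rendered_width_px(px_per_mm)
        R = _stroke_radius(w)
        L_c = spec.length_mm * px_per_mm  # centreline length
        th = math.radians(spec.orientation_deg)
        u = (math.sin(th), math.cos(th))  # (drow, dcol)
        p0 = _align_start(spec.position, u, w)
        if spec.shape == "straight":
            p1 = (p0[0] + L_c * u[0], p0[1] + L_c * u[1])
            painted = _paint_segment(canvas, p0, p1, R)
            length_px = L_c
        elif spec.shape == "arc":
            sag = spec.arc_sagitta_frac * L_c
            arc_r = (L_c ** 2 / 4.0 + sag ** 2) / (2.0 * sag)
            half = math.asin(min((L_c / 2.0) / arc_r, 1.0))
            mid = (p0[0] + (L_c / 2) * u[0], p0[1] + (L_c / 2) * u[1])
            n = (-u[1], u[0])
            centre = (mid[0] + (arc_r - sag) * n[0], mid[1] + (arc_r - sag) * n[1])
            base = math.atan2(-n[0], -n[1])
            painted = _paint_arc(canvas, centre, arc_r, base - half, base + half, R)
            length_px = 2 * arc_r * half
        else:
            raise ValueError(f"unknown wire shape {spec.shape!r}")
        if not painted.any():
            raise ValueError("wire rendered outside the canvas")
        if (painted & canvas).any():
            raise ValueError("wires overlap")
        # reject wires clipped by the canvas edge: the painted bounding box
        # must not touch the border
        rows, cols = np.nonzero(painted)
        if (rows.min() == 0 or cols.min() == 0
                or rows.max() == canvas_shape[0] - 1
                or cols.max() == canvas_shape[1] - 1):
            raise ValueError("wire does not fit in the canvas")
        canvas |= painted
        lengths.append(length_px / px_per_mm)
        diams.append(w / px_per_mm)
    truth = SceneTruth(object_count=len(specs))
    if specs:
        lengths = np.array(lengths)
        diams = np.array(diams)
        truth.total_length_mm = float(lengths.sum())
        truth.weighted_avg_diameter_mm = float((lengths * diams).sum() / lengths.sum())
        truth.surface_area_mm2 = float((math.pi * diams * lengths).sum())
        truth.volume_mm3 = float((math.pi * (diams / 2.0) ** 2 * lengths).sum())
    pixels = np.where(canvas, np.uint8(wire_level), np.uint8(background_level))
    return GreyImage(pixels, px_per_mm=px_per_mm), truth


def _align_start(position, u, width_px) -> Tuple[float, float]:
    """Snap the centreline start so axis-aligned strokes render at the exact
    integer width: integer coordinates for odd widths, half-integer transverse
    offset for even widths."""
    r, c = float(position[0]), float(position[1])
    horizontal = abs(u[0]) < 1e-9
    vertical = abs(u[1]) < 1e-9
    if horizontal or vertical:
        if width_px % 2 == 0:
            if horizontal:
                r = math.floor(r) + 0.5
            else:
                c = math.floor(c) + 0.5
        else:
            if horizontal:
                r = round(r)
            else:
                c = round(c)
    return (r, c)


def _auto_canvas(specs: Sequence[WireSpec], px_per_mm: float) -> Tuple[int, int]:
    h = w = 64
    for spec in specs:
        L = spec.length_mm * px_per_mm
        wd = spec.rendered_width_px(px_per_mm)
        th = math.radians(spec.orientation_deg)
        dr = abs(L * math.sin(th)) + wd
        dc = abs(L * math.cos(th)) + wd
        if spec.shape == "arc":
            sag = spec.arc_sagitta_frac * L
            dr += sag
            dc += sag
        h = max(h, int(spec.position[0] + dr) + wd + 8)
        w = max(w, int(spec.position[1] + dc) + wd + 8)
    return h, w


def sample_wire_scene(rng: np.random.Generator,
                      px_per_mm: float = DEFAULT_PX_PER_MM,
                      n_wires: Optional[int] = None
                      ) -> Tuple[GreyImage, SceneTruth]:
    """Draw a random wire-scan scene from the default study conditions.

    3-6 horizontal wires with gauges sampled from the AWG set, lengths
    100-160 mm (physical validation wires were ~305 mm; long enough that a
    thin wire is never mistaken for debris by the 8 mm^2 background filter),
    stacked with clearances; every scene includes the thickest gauge
    (AWG 10) so that, as in physical wire scans, scene totals are dominated
    by well-resolved wires.
    """
    gauges = sorted(AWG_DIAMETERS_MM)  # [10, 16, 22, 28, 32, 40]
    if n_wires is None:
        n_wires = int(rng.integers(3, 7))
    chosen = [10] + list(rng.choice(gauges[1:], size=n_wires - 1, replace=True))
    specs = []
    row = 40.0
    max_len = 0.0
    for g in chosen:
        d_mm = AWG_DIAMETERS_MM[int(g)]
        length = float(rng.uniform(100.0, 160.0))
        w = max(1, int(round(d_mm * px_per_mm)))
        row += w / 2.0
        col = 40.0 + float(rng.uniform(0, 60))
        specs.append(WireSpec(d_mm, length, position=(row, col)))
        row += w / 2.0 + float(rng.uniform(25, 60))
        max_len = max(max_len, col + length * px_per_mm + w)
    shape = (int(row + 60), int(max_len + 60))
    return render_wires(specs, px_per_mm=px_per_mm, canvas_shape=shape)


def render_branched_root(main_length_px: int, main_width_px: int,
                         laterals: Sequence[Tuple[int, int, int]],
                         px_per_mm: Optional[float] = None,
                         background_level: int = BACKGROUND_LEVEL,
                         wire_level: int = WIRE_LEVEL
                         ) -> Tuple[GreyImage, Dict[str, object]]:
    """A horizontal main axis with vertical laterals hanging from it.

    ``laterals`` is a list of (col_offset, length_px, width_px); laterals
    attach to the main axis and grow downward (+y).  Returns the image and a
    truth dict with expected tips, branch points and per-order centreline
    lengths for diameter-bin tests.
    """
    main_width_px = int(main_width_px)
    margin = 2 * main_width_px + 16
    height = margin + max([l for _, l, _ in laterals], default=0) + margin
    width = margin + main_length_px + margin
    canvas = np.zeros((height, width), dtype=bool)
    r_main = margin if main_width_px % 2 == 1 else margin + 0.5
    p0 = (r_main, float(margin))
    p1 = (r_main, float(margin + main_length_px))
    main = _paint_segment(canvas, p0, p1, _stroke_radius(main_width_px))
    canvas |= main
    last_end = -1e9
    for col_off, lat_len, lat_w in laterals:
        lat_w = int(lat_w)
        if lat_w > main_width_px:
            raise ValueError("lateral wider than the main axis")
        col = margin + col_off if lat_w % 2 == 1 else margin + col_off + 0.5
        if col - lat_w / 2.0 <= last_end:
            raise ValueError("overlapping laterals")
        last_end = col + lat_w / 2.0 + 1
        q0 = (r_main, col)
        q1 = (r_main + main_width_px / 2.0 + lat_len, col)
        canvas |= _paint_segment(canvas, q0, q1, _stroke_radius(lat_w))
    pixels = np.where(canvas, np.uint8(wire_level), np.uint8(background_level))
    truth = {
        "tips": len(laterals) + 2,
        "branch_points": len(laterals),
        "main_width_px": main_width_px,
        "lateral_widths_px": [int(w) for _, _, w in laterals],
        # expected skeletal lengths: centreline plus rendered cap extents.
        # A lateral's skeletal path additionally crosses half the main axis
        # to reach its ridge; those crossing pixels carry the main axis's
        # radius, so whether they land in the fine or coarse diameter bin
        # depends on the bin edge -- "junction_crossing_px" bounds that share.
        "main_skel_length_px": float(
            main_length_px + 2 * _cap_extension_px(main_width_px,
                                                   _stroke_radius(main_width_px))),
        "lateral_skel_lengths_px": [
            float(l + _cap_extension_px(int(w), _stroke_radius(int(w))))
            for _, l, w in laterals],
        "junction_crossing_px": len(laterals) * (main_width_px / 2.0 + 1.0),
    }
    return GreyImage(pixels, px_per_mm=px_per_mm), truth


def corrupt(img: GreyImage, speckle_count: int = 0, speckle_size_px: int = 2,
            hole_count: int = 0, hole_size_px: int = 1,
            seed: int = 0,
            background_level: int = BACKGROUND_LEVEL,
            wire_level: int = WIRE_LEVEL) -> GreyImage:
    """Add dark background speckles and bright in-root holes, deterministically.

    Speckles emulate soil particles left after washing; holes emulate bright
    spots inside roots that threshold to background.  Sizes are areas in px;
    speckles are placed clear of the roots and holes strictly inside them,
    so size-thresholded filtering can undo the corruption exactly.
    """
    from scipy import ndimage

    rng = np.random.default_rng(seed)
    px = img.pixels.copy()
    root = px <= (wire_level + background_level) // 2
    h, w = px.shape

    side = max(1, int(math.ceil(math.sqrt(speckle_size_px))))
    # background positions far from roots and the border
    bg_dist = ndimage.distance_transform_edt(~root)
    safe_bg = bg_dist > side + 2
    safe_bg[: side + 2, :] = safe_bg[-(side + 2):, :] = False
    safe_bg[:, : side + 2] = safe_bg[:, -(side + 2):] = False
    candidates = np.argwhere(safe_bg)
    rng.shuffle(candidates)
    placed = 0
    centres: list = []
    for r, c in candidates:
        if placed >= speckle_count:
            break
        if any(abs(r - pr) <= 2 * side + 2 and abs(c - pc) <= 2 * side + 2
               for pr, pc in centres):
            continue
        block = px[r:r + side, c:c + side]
        if (block == background_level).all():
            area = block.size
            if area > speckle_size_px:
                block.flat[:speckle_size_px] = wire_level
            else:
                block[:] = wire_level
            centres.append((r, c))
            placed += 1

    hside = max(1, int(math.ceil(math.sqrt(hole_size_px))))
    interior = ndimage.binary_erosion(root, iterations=hside + 1)
    candidates = np.argwhere(interior)
    rng.shuffle(candidates)
    placed = 0
    centres = []
    for r, c in candidates:
        if placed >= hole_count:
            break
        if any(abs(r - pr) <= 2 * hside + 2 and abs(c - pc) <= 2 * hside + 2
               for pr, pc in centres):
            continue
        block = px[r:r + hside, c:c + hside]
        if (block == wire_level).all():
            if block.size > hole_size_px:
                block.flat[:hole_size_px] = background_level
            else:
                block[:] = background_level
            centres.append((r, c))
            placed += 1
    return GreyImage(px, px_per_mm=img.px_per_mm)
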