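"""Segmentation of root pixels from a greyscale scan.

Global thresholding (dark roots on a bright background, or inverted for
backlit crown images), connected-component noise filtering, hole filling and
optional Ramer–Douglas–Peucker contour smoothing.  Root components and
background components both use 8-connectivity; a one-pixel gap on a diagonal
therefore connects a cavity to the outside and stops it counting as a hole.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import ndimage
from skimage.draw import polygon as draw_polygon
from skimage.draw import polygon_perimeter
from skimage.measure import approximate_polygon

from .image_io import GreyImage

__all__ = [
    "RootMask",
    "threshold",
    "filter_background_noise",
    "fill_holes",
    "smooth_contours",
    "trace_contour",
    "segment",
]

_EIGHT = np.ones((3, 3), dtype=int)


@dataclass
class RootMask:
    """Binary root segmentation; same shape as the source image."""

    pixels: np.ndarray
    px_per_mm: Optional[float] = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels).astype(bool)
        if self.pixels.ndim != 2:
            raise ValueError("RootMask requires a 2-D array")

    @property
    def shape(self):
        return self.pixels.shape

    def area_px(self) -> int:
        return int(self.pixels.sum())


def _area_to_px2(area: float, px_per_mm: Optional[float]) -> float:
    """Interpret an area as mm^2 when a resolution is known, else px^2."""
    if px_per_mm is None:
        return float(area)
    return float(area) * px_per_mm ** 2


def threshold(img: GreyImage, level: int, invert: bool = False) -> RootMask:
    """Global threshold: a pixel is root iff intensity <= level (or > level
    when ``invert`` is set)."""
    if not 0 <= level <= 255:
        raise ValueError("threshold level must be in [0, 255]")
    px = img.pixels > level if invert else img.pixels <= level
    return RootMask(px, px_per_mm=img.px_per_mm)


def filter_background_noise(mask: RootMask, max_size: float) -> RootMask:
    """Remove 8-connected root components with area <= max_size.

    ``max_size`` is mm^2 when the mask carries a resolution, else px^2;
    soil particles and other debris are typically a few mm^2.
    """
    max_px = _area_to_px2(max_size, mask.px_per_mm)
    if max_px <= 0:
        return RootMask(mask.pixels.copy(), mask.px_per_mm)
    labels, n = ndimage.label(mask.pixels, structure=_EIGHT)
    if n == 0:
        return RootMask(mask.pixels.copy(), mask.px_per_mm)
    sizes = np.bincount(labels.ravel())
    keep = sizes > max_px
    keep[0] = False
    return RootMask(keep[labels], mask.px_per_mm)


def fill_holes(mask: RootMask, max_size: float) -> RootMask:
    """Fill enclosed background cavities with area <= max_size.

    A hole is an 8-connected background component that does not touch the
    image border, so its entire outer boundary is root.
    """
    max_px = _area_to_px2(max_size, mask.px_per_mm)
    if max_px <= 0:
        return RootMask(mask.pixels.copy(), mask.px_per_mm)
    bg = ~mask.pixels
    labels, n = ndimage.label(bg, structure=_EIGHT)
    if n == 0:
        return RootMask(mask.pixels.copy(), mask.px_per_mm)
    border = np.unique(
        np.concatenate([labels[0, :], labels[-1, :], labels[:, 0], labels[:, -1]])
    )
    sizes = np.bincount(labels.ravel())
    fill = (sizes <= max_px) & (sizes > 0)
    fill[0] = False
    fill[border] = False
    out = mask.pixels | fill[labels]
    return RootMask(out, mask.px_per_mm)


# Moore-neighbour contour tracing in pixel-centre coordinates.  The eight
# neighbour offsets in clockwise order starting East (row, col), for an image
# with y downward.
_MOORE = [(0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1), (-1, 0), (-1, 1)]


def trace_contour(component: np.ndarray, start: tuple) -> np.ndarray:
    """Trace the closed outer boundary of an 8-connected component.

    ``start`` must be the lexicographically smallest (row, col) pixel of the
    component.  Returns an (N, 2) array of boundary pixel centres in order;
    a single-pixel component yields a length-1 contour.
    """
    h, w = component.shape
    r0, c0 = start
    limit = 4 * int(component.sum()) + 8

    def next_from(cur, prev_dir):
        for k in range(1, 9):
            d = (prev_dir + k) % 8
            dr, dc = _MOORE[d]
            r, c = cur[0] + dr, cur[1] + dc
            if 0 <= r < h and 0 <= c < w and component[r, c]:
                return (r, c), d
        return None, None

    # we arrive at the start pixel coming from the West, so scanning begins
    # clockwise from the North-West; the start is the topmost-leftmost pixel
    second, _ = next_from((r0, c0), 4)
    if second is None:  # isolated pixel
        return np.array([[r0, c0]], dtype=float)
    contour = [(r0, c0)]
    cur, prev_dir = (r0, c0), 4
    while True:
        nxt, move = next_from(cur, prev_dir)
        # Jacob's criterion: stop when about to retrace start -> second
        if cur == (r0, c0) and len(contour) > 1 and nxt == second:
            break
        contour.append(nxt)
        cur, prev_dir = nxt, (move + 4) % 8
        if len(contour) > limit:
            break  # safety net; cannot happen on consistent input
    if len(contour) > 1 and contour[-1] == contour[0]:
        contour.pop()
    return np.array(contour, dtype=float)


def component_contours(mask_px: np.ndarray):
    """Yield (outer, [inner...]) traced contours for every root component.

    Inner contours are the traced boundaries of enclosed holes, in hole-pixel
    coordinates (the cavity itself), consistent with 8-connected holes.
    """
    labels, n = ndimage.label(mask_px, structure=_EIGHT)
    if n == 0:
        return
    # hole labelling once for the whole mask
    bg_labels, m = ndimage.label(~mask_px, structure=_EIGHT)
    border = np.unique(np.concatenate(
        [bg_labels[0, :], bg_labels[-1, :], bg_labels[:, 0], bg_labels[:, -1]]))
    is_hole = np.ones(m + 1, dtype=bool)
    is_hole[0] = False
    is_hole[border] = False
    objects = ndimage.find_objects(labels)
    hole_objects = ndimage.find_objects(bg_labels)
    for idx in range(1, n + 1):
        sl = objects[idx - 1]
        comp = labels[sl] == idx
        rows, cols = np.nonzero(comp)
        k = np.lexsort((cols, rows))[0]
        outer = trace_contour(comp, (rows[k], cols[k]))
        outer += [sl[0].start, sl[1].start]
        # holes whose bounding box sits inside this component's box
        inners = []
        filled = ndimage.binary_fill_holes(comp)
        for hidx in range(1, m + 1):
            if not is_hole[hidx]:
                continue
            hsl = hole_objects[hidx - 1]
            hr, hc = np.nonzero(bg_labels[hsl] == hidx)
            hr = hr + hsl[0].start
            hc = hc + hsl[1].start
            r, c = hr[0] - sl[0].start, hc[0] - sl[1].start
            if not (0 <= r < filled.shape[0] and 0 <= c < filled.shape[1] and filled[r, c]):
                continue
            hcomp = np.zeros((hsl[0].stop - hsl[0].start, hsl[1].stop - hsl[1].start), bool)
            hcomp[hr - hsl[0].start, hc - hsl[1].start] = True
            hrows, hcols = np.nonzero(hcomp)
            hk = np.lexsort((hcols, hrows))[0]
            inner = trace_contour(hcomp, (hrows[hk], hcols[hk]))
            inner += [hsl[0].start, hsl[1].start]
            inners.append(inner)
        yield outer, inners


def _rasterize(poly: np.ndarray, shape) -> np.ndarray:
    """Filled polygon (pixel-centre vertices) including its boundary pixels."""
    out = np.zeros(shape, bool)
    if len(poly) == 1:
        out[int(poly[0, 0]), int(poly[0, 1])] = True
        return out
    rr, cc = draw_polygon(poly[:, 0], poly[:, 1], shape=shape)
    out[rr, cc] = True
    rr, cc = polygon_perimeter(poly[:, 0], poly[:, 1], shape=shape, clip=True)
    out[rr, cc] = True
    return out


def smooth_contours(mask: RootMask, tolerance_px: float) -> RootMask:
    """Simplify each component's contours with the Ramer–Douglas–Peucker
    algorithm and re-rasterize.

    Small boundary roughness seeds short invalid lateral roots during
    skeletonization; simplifying the contour within ``tolerance_px`` removes
    it.  Tolerance 0 returns the mask unchanged.  Values above 2.0 can alter
    the root topology and trigger a warning.
    """
    if tolerance_px < 0:
        raise ValueError("tolerance_px must be >= 0")
    if tolerance_px > 2.0:
        warnings.warn("contour smoothing tolerance > 2.0 px may alter root topology")
    if tolerance_px == 0:
        return RootMask(mask.pixels.copy(), mask.px_per_mm)
    out = np.zeros(mask.shape, bool)
    for outer, inners in component_contours(mask.pixels):
        closed = np.vstack([outer, outer[:1]]) if len(outer) > 2 else outer
        simple = approximate_polygon(closed, tolerance_px)
        out |= _rasterize(simple, mask.shape)
        for inner in inners:
            closed = np.vstack([inner, inner[:1]]) if len(inner) > 2 else inner
            simple = approximate_polygon(closed, tolerance_px)
            # hole contour vertices are cavity pixels; the rasterized polygon
            # (boundary included) is exactly the background to carve out
            out &= ~_rasterize(simple, mask.shape)
    return RootMask(out, mask.px_per_mm)


def segment(img: GreyImage, config) -> RootMask:
    """Full segmentation stage: threshold, then background-noise filtering,
    hole filling and contour smoothing as enabled by ``config``.

    The order is fixed: threshold -> background filter -> hole fill ->
    smoothing.
    """
    px_per_mm = config.resolved_px_per_mm() or img.px_per_mm
    mask = threshold(
        GreyImage(img.pixels, px_per_mm=px_per_mm),
        config.threshold_level,
        config.invert,
    )
    if config.filter_background:
        mask = filter_background_noise(mask, config.max_component_size)
    if config.fill_holes:
        mask = fill_holes(mask, config.max_hole_size)
    if config.edge_smoothing:
        mask = smooth_contours(mask, config.rdp_tolerance_px)
    return mask
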