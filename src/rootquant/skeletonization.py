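"""Radius-annotated medial axis from a binary root mask.

The skeleton is built in four steps: an exact Euclidean distance transform;
ridge detection on the distance map (a pixel whose value exceeds both
neighbours of at least one opposite-direction pair); steepest-ascent walks
that connect detached ridge fragments — lateral-root ridges end short of the
parent ridge because the distance map keeps rising toward it — and Guo–Hall
two-subiteration thinning down to one-pixel width.  Each surviving skeleton
pixel keeps its distance-map value, the local root radius in pixels, which
everything downstream (diameters, surface area, volume, pruning) relies on.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field
from typing import Dict, Optional, Set, Tuple

import numpy as np
from scipy import ndimage
from skimage.morphology import thin as _guo_hall_thin

from .segmentation import RootMask

__all__ = [
    "RadiusSkeleton",
    "distance_transform",
    "detect_ridges",
    "connect_ridges",
    "thin_skeleton",
    "build_skeleton",
]

_EIGHT = np.ones((3, 3), dtype=int)

Pixel = Tuple[int, int]

# fixed neighbour order for deterministic tie-breaking: E, NE, N, NW, W, SW, S, SE
_ASCENT_ORDER = [(0, 1), (-1, 1), (-1, 0), (-1, -1), (0, -1), (1, -1), (1, 0), (1, 1)]


@dataclass
class RadiusSkeleton:
    """One-pixel-wide 8-connected medial axis with per-pixel root radius."""

    pixels: Set[Pixel]
    radius_px: Dict[Pixel, float]
    shape: Tuple[int, int]
    px_per_mm: Optional[float] = None

    def __post_init__(self) -> None:
        self.pixels = set(self.pixels)

    def neighbours(self, p: Pixel):
        r, c = p
        return [(r + dr, c + dc) for dr, dc in _ASCENT_ORDER
                if (r + dr, c + dc) in self.pixels]

    def to_array(self) -> np.ndarray:
        out = np.zeros(self.shape, bool)
        if self.pixels:
            rows, cols = zip(*self.pixels)
            out[list(rows), list(cols)] = True
        return out

    def component_count(self) -> int:
        return int(ndimage.label(self.to_array(), structure=_EIGHT)[1])


def distance_transform(mask: RootMask) -> np.ndarray:
    """Exact Euclidean distance (px) from each root pixel to the nearest
    background pixel centre; 0 on background."""
    return ndimage.distance_transform_edt(mask.pixels)


def detect_ridges(dmap: np.ndarray) -> np.ndarray:
    """Ridge pixels of the distance map.

    A root pixel is a ridge pixel when its value strictly exceeds both
    neighbours of at least one opposite-direction pair (E/W, N/S, NE/SW,
    NW/SE).  Roots of even pixel width have a two-pixel distance-map plateau
    along the centre with no strict ridge, so plateau local maxima (>= all
    eight neighbours and > at least one) are also accepted; the resulting
    two-pixel-wide ridge is reduced by thinning.  Off-image neighbours count
    as background (value 0).
    """
    d = np.pad(dmap, 1, mode="constant")
    c = d[1:-1, 1:-1]
    e, w = d[1:-1, 2:], d[1:-1, :-2]
    n, s = d[:-2, 1:-1], d[2:, 1:-1]
    ne, sw = d[:-2, 2:], d[2:, :-2]
    nw, se = d[:-2, :-2], d[2:, 2:]

    ridge = (c > e) & (c > w)
    ridge |= (c > n) & (c > s)
    ridge |= (c > ne) & (c > sw)
    ridge |= (c > nw) & (c > se)
    # plateau rule: weak local maximum that dominates at least one neighbour
    ge_all = ((c >= e) & (c >= w) & (c >= n) & (c >= s)
              & (c >= ne) & (c >= sw) & (c >= nw) & (c >= se))
    gt_any = ((c > e) | (c > w) | (c > n) | (c > s)
              | (c > ne) | (c > sw) | (c > nw) | (c > se))
    ridge |= ge_all & gt_any
    return ridge & (c > 0)


def _ascend(start: Pixel, dmap: np.ndarray, mask_px: np.ndarray,
            skeleton: np.ndarray, cap: int):
    """One steepest-ascent walk; returns the pixels to add (may be empty)."""
    h, w = dmap.shape
    path = []
    visited = {start}
    cur = start
    for _ in range(cap):
        best = None
        best_val = -1.0
        r, c = cur
        for dr, dc in _ASCENT_ORDER:
            nr, nc = r + dr, c + dc
            if 0 <= nr < h and 0 <= nc < w and mask_px[nr, nc]:
                v = dmap[nr, nc]
                if v > best_val:
                    best_val = v
                    best = (nr, nc)
        if best is None or best in visited:
            break
        if skeleton[best]:
            return path  # reached (or started adjacent to) the backbone
        if best_val < dmap[cur]:
            break  # only downhill left: the ascent stalls
        path.append(best)
        visited.add(best)
        cur = best
    return path  # ascent stalled; keep the walked pixels


def _merge_components(dmap: np.ndarray, mask_px: np.ndarray,
                      skeleton: np.ndarray) -> None:
    """Force one skeleton component per mask component.

    Best-first search from the largest skeleton component over the mask,
    preferring high distance-map values (deterministic coordinate
    tie-breaks); the first path reaching another skeleton component is added,
    until the component counts agree.  In practice the ascent walks already
    connect everything and this is a no-op safety net.
    """
    mask_labels, n_mask = ndimage.label(mask_px, structure=_EIGHT)
    h, w = dmap.shape
    for midx in range(1, n_mask + 1):
        while True:
            comp_mask = mask_labels == midx
            skel_labels, n_skel = ndimage.label(skeleton & comp_mask, structure=_EIGHT)
            if n_skel <= 1:
                break
            sizes = np.bincount(skel_labels.ravel())
            sizes[0] = 0
            main = int(np.argmax(sizes))
            seeds = np.argwhere(skel_labels == main)
            heap = [(-dmap[r, c], r, c) for r, c in seeds]
            heapq.heapify(heap)
            parent: Dict[Pixel, Optional[Pixel]] = {(r, c): None for r, c in seeds}
            target = None
            while heap:
                _, r, c = heapq.heappop(heap)
                lbl = skel_labels[r, c]
                if lbl not in (0, main):
                    target = (r, c)
                    break
                for dr, dc in _ASCENT_ORDER:
                    nr, nc = r + dr, c + dc
                    if (0 <= nr < h and 0 <= nc < w and comp_mask[nr, nc]
                            and (nr, nc) not in parent):
                        parent[(nr, nc)] = (r, c)
                        heapq.heappush(heap, (-dmap[nr, nc], nr, nc))
            if target is None:  # cannot happen: mask component is connected
                break
            p = parent[target]
            while p is not None and not skeleton[p]:
                skeleton[p] = True
                p = parent[p]


def connect_ridges(dmap: np.ndarray, ridges: np.ndarray,
                   mask_px: Optional[np.ndarray] = None) -> np.ndarray:
    """Connect ridge fragments into one skeleton per mask component.

    From every ridge pixel a steepest-ascent walk is taken toward the highest
    8-neighbour on the distance map, adding the visited pixels, until an
    existing skeleton pixel is reached or the ascent stalls.  A best-first
    fallback then guarantees the component-count postcondition.
    """
    if mask_px is None:
        mask_px = dmap > 0
    skeleton = ridges.copy()
    cap = int(mask_px.sum()) + 1
    for r, c in np.argwhere(ridges):
        for p in _ascend((int(r), int(c)), dmap, mask_px, skeleton, cap):
            skeleton[p] = True
    _merge_components(dmap, mask_px, skeleton)
    return skeleton


def thin_skeleton(pixels: np.ndarray) -> np.ndarray:
    """Guo–Hall two-subiteration thinning to one-pixel width, iterated to
    stability; preserves 8-connectivity and component count."""
    return _guo_hall_thin(pixels.astype(bool))


def collapse_triangles(pixels: Set[Pixel]) -> Set[Pixel]:
    """Remove redundant corner pixels left by thinning and spoke pruning.

    Where ridge branches meet (typically at blunt root ends), thinning and
    spur deletion can leave a pixel whose 8-neighbours are already mutually
    connected without it — a 3-pixel triangle corner, or a one-pixel stub
    riding on three consecutive path pixels.  Such a pixel carries no path
    information but manufactures false loops and hides the real tip, so it is
    deleted; connectivity is preserved because its neighbours stay connected.
    Genuine branch points survive: their arms fall into separate neighbour
    clusters.  Scan-order processing, cascaded until stable.
    """

    def degree(q: Pixel, s: Set[Pixel]) -> int:
        return sum((q[0] + dr, q[1] + dc) in s for dr, dc in _ASCENT_ORDER)

    def redundant(nb) -> bool:
        if len(nb) == 2:  # triangle corner: the two neighbours touch
            (a, b) = nb
            return max(abs(a[0] - b[0]), abs(a[1] - b[1])) == 1
        if len(nb) == 3:  # stub riding on three consecutive collinear pixels
            nb = sorted(nb)
            same_row = nb[0][0] == nb[1][0] == nb[2][0]
            same_col = nb[0][1] == nb[1][1] == nb[2][1]
            if same_row:
                return nb[2][1] - nb[0][1] == 2
            if same_col:
                return nb[2][0] - nb[0][0] == 2
        return False

    out = set(pixels)
    changed = True
    while changed:
        changed = False
        for p in sorted(out):
            if p not in out:
                continue
            nb = [(p[0] + dr, p[1] + dc) for dr, dc in _ASCENT_ORDER
                  if (p[0] + dr, p[1] + dc) in out]
            # only collapse corners hanging off a junction, never plain
            # staircase bends of a simple path
            if redundant(nb) and any(degree(q, out) >= 3 for q in nb):
                out.discard(p)
                changed = True
    return out


def build_skeleton(mask: RootMask) -> RadiusSkeleton:
    """Full skeletonization: distance transform, ridge detection,
    steepest-ascent connection, thinning; radii read off the distance map."""
    dmap = distance_transform(mask)
    ridges = detect_ridges(dmap)
    connected = connect_ridges(dmap, ridges, mask.pixels)
    thinned = thin_skeleton(connected)
    pix = collapse_triangles(
        {(int(r), int(c)) for r, c in np.argwhere(thinned)})
    radii = {p: float(dmap[p]) for p in pix}
    return RadiusSkeleton(set(pix), radii, mask.shape, px_per_mm=mask.px_per_mm)
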