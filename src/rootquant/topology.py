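"""Skeleton topology: tips, branch points, segments, and root pruning.

A thinned skeleton is classified by 8-neighbour count: one neighbour makes a
root tip, three or more a branch point, two an ordinary segment pixel (an
isolated pixel counts as a tip).  Segments run between two endpoints (tip or
branch).  Root pruning removes short branch-to-tip segments — artefactual
laterals created by boundary roughness are never longer than the radius of
the parent root they spring from — and iterates, because deleting a spur can
merge segments across its former branch point and expose new prunable tips.
Pruning edits the skeleton only; the segmented mask is untouched.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Set, Tuple

from .skeletonization import Pixel, RadiusSkeleton, collapse_triangles

__all__ = [
    "TIP",
    "BRANCH",
    "SEGMENT",
    "RootSegment",
    "TopologyMap",
    "classify_pixels",
    "prune",
    "count_tips",
    "count_branch_points",
]

TIP = "TIP"
BRANCH = "BRANCH"
SEGMENT = "SEGMENT"

_SQRT2 = math.sqrt(2.0)


def _step(a: Pixel, b: Pixel) -> float:
    return _SQRT2 if (a[0] != b[0] and a[1] != b[1]) else 1.0


def path_length(path: List[Pixel]) -> float:
    """Sum of inter-pixel Euclidean steps (1 orthogonal, sqrt(2) diagonal)."""
    return sum(_step(a, b) for a, b in zip(path, path[1:]))


@dataclass
class RootSegment:
    """Ordered pixel path between two endpoints (each a tip or branch)."""

    path: List[Pixel]
    end_types: Tuple[str, str]

    @property
    def length_px(self) -> float:
        return path_length(self.path)

    @property
    def start(self) -> Pixel:
        return self.path[0]

    @property
    def end(self) -> Pixel:
        return self.path[-1]


@dataclass
class TopologyMap:
    """Per-pixel labels plus the enumerated segment list."""

    label: Dict[Pixel, str]
    segments: List[RootSegment]

    def tips(self) -> List[Pixel]:
        return [p for p, l in self.label.items() if l == TIP]

    def branch_points(self) -> List[Pixel]:
        return [p for p, l in self.label.items() if l == BRANCH]


def classify_pixels(skel: RadiusSkeleton) -> TopologyMap:
    """Label every skeleton pixel and trace all segments.

    Closed loops with no tip or branch point (possible for ring-shaped
    skeletons) are traced as a single cyclic segment and are never prunable.
    """
    label: Dict[Pixel, str] = {}
    nbrs: Dict[Pixel, List[Pixel]] = {}
    for p in skel.pixels:
        nb = skel.neighbours(p)
        nbrs[p] = nb
        if len(nb) <= 1:
            label[p] = TIP
        elif len(nb) == 2:
            label[p] = SEGMENT
        else:
            label[p] = BRANCH

    segments: List[RootSegment] = []
    visited_edges: Set[frozenset] = set()
    endpoints = sorted(p for p, l in label.items() if l != SEGMENT)
    for e in endpoints:
        for n in sorted(nbrs[e]):
            edge = frozenset((e, n))
            if edge in visited_edges:
                continue
            path = [e, n]
            visited_edges.add(edge)
            prev, cur = e, n
            while label[cur] == SEGMENT:
                nxt = next(q for q in nbrs[cur] if q != prev)
                visited_edges.add(frozenset((cur, nxt)))
                path.append(nxt)
                prev, cur = cur, nxt
            segments.append(RootSegment(path, (label[e], label[cur])))
    # leftover pure cycles: every pixel degree 2, unvisited
    traced = {p for s in segments for p in s.path}
    remaining = sorted(p for p in skel.pixels if p not in traced)
    seen: Set[Pixel] = set()
    for p in remaining:
        if p in seen or label[p] != SEGMENT:
            continue
        path = [p]
        seen.add(p)
        prev, cur = None, p
        while True:
            nxt = next((q for q in sorted(nbrs[cur]) if q != prev and q not in seen),
                       None)
            if nxt is None:
                break
            path.append(nxt)
            seen.add(nxt)
            prev, cur = cur, nxt
        path.append(p)  # close the loop
        segments.append(RootSegment(path, (SEGMENT, SEGMENT)))
    return TopologyMap(label, segments)


def count_tips(topo: TopologyMap) -> int:
    return sum(1 for l in topo.label.values() if l == TIP)


def count_branch_points(topo: TopologyMap) -> int:
    """Number of branch points, counting 8-connected clusters of
    branch-labelled pixels as one.

    A lateral meeting its parent at right angles produces several mutually
    adjacent pixels with three or more skeletal neighbours; they mark the
    same anatomical branch point, so adjacent branch pixels are merged
    before counting.  At ordinary Y-shaped junctions the cluster is a single
    pixel and this equals the raw pixel count.
    """
    branches = {p for p, l in topo.label.items() if l == BRANCH}
    seen: Set[Pixel] = set()
    count = 0
    for p in sorted(branches):
        if p in seen:
            continue
        count += 1
        stack = [p]
        seen.add(p)
        while stack:
            r, c = stack.pop()
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    q = (r + dr, c + dc)
                    if q in branches and q not in seen:
                        seen.add(q)
                        stack.append(q)
    return count


def _prunable(seg: RootSegment, radii: Dict[Pixel, float], threshold_px: float):
    """(sort key, branch pixel) if the segment is a deletable spur, else None.

    Deletable: exactly one end is a branch point and the other a tip, and the
    path length (branch centre to tip centre) does not exceed the branch
    pixel's radius plus the user threshold.  Branch-to-branch segments and
    tip-to-tip components are never deleted.
    """
    kinds = seg.end_types
    if sorted(kinds) != [BRANCH, TIP]:
        return None
    branch = seg.start if kinds[0] == BRANCH else seg.end
    length = seg.length_px
    if length > radii[branch] + threshold_px:
        return None
    return (length - radii[branch], branch), branch


def prune(skel: RadiusSkeleton, topo: TopologyMap,
          threshold_px: float) -> Tuple[RadiusSkeleton, TopologyMap]:
    """Iteratively delete invalid lateral roots from the skeleton.

    Each pass evaluates every branch-to-tip segment of the current topology
    and deletes all that fail the length test (tip and interior pixels; the
    branch pixel survives).  Deletions within a pass are independent —
    prunable segments can share at most their branch endpoints, which are
    kept — so no ordering is needed.  Branch pixels are then relabelled by
    their new neighbour counts and passes repeat, because merging segments
    across a vanished branch point can expose new prunable tips.
    """
    pixels = set(skel.pixels)
    radii = dict(skel.radius_px)
    current = topo
    while True:
        doomed: Set[Pixel] = set()
        for seg in current.segments:
            hit = _prunable(seg, radii, threshold_px)
            if hit is not None:
                _, branch = hit
                doomed.update(p for p in seg.path if p != branch)
        if not doomed:
            break
        pixels.difference_update(doomed)
        # pruning can expose redundant corner pixels where spokes met
        pixels = collapse_triangles(pixels)
        radii = {p: radii[p] for p in pixels}
        current = classify_pixels(RadiusSkeleton(pixels, radii, skel.shape))
    out_skel = RadiusSkeleton(pixels, radii, skel.shape, px_per_mm=skel.px_per_mm)
    return out_skel, classify_pixels(out_skel)
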