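# Methods

## Scope and model

`rootquant` measures washed plant roots from high-contrast raster scans
(flatbed scanner with a transparency unit, or a backlit imaging rig).  The
central object is a radius-annotated medial axis: every skeleton pixel
carries the Euclidean distance to the nearest background pixel, which is
the local root radius.  All length-, diameter-, area- and volume-type
traits derive from this one structure plus the segmented mask.

The pipeline is:

1. **Segmentation.**  Global greyscale thresholding (a pixel is root iff
   intensity ≤ level; inversion available for bright-root images), then
   optional connected-component filtering of background debris (area ≤ a
   user maximum, default protocol 8 mm²), optional filling of enclosed
   holes, and optional Ramer–Douglas–Peucker contour smoothing.  Root and
   background components both use 8-connectivity, so a cavity joined to the
   outside through a single diagonal gap is not a hole.  The stage order is
   fixed: threshold → background filter → hole fill → smoothing.
2. **Skeletonization.**  Exact Euclidean distance transform
   (`scipy.ndimage.distance_transform_edt`); ridge detection; steepest-ascent
   connection of detached ridge fragments; Guo–Hall two-subiteration
   thinning (`skimage.morphology.thin`) to one-pixel width; a final
   redundant-corner collapse (below).  Radii are read off the distance map.
3. **Topology.**  8-neighbour counts label each skeleton pixel as tip (≤1
   neighbour), branch (≥3) or segment pixel (2); segments are traced
   between endpoints.  Root pruning iteratively deletes branch-to-tip
   segments no longer than the branch pixel's radius plus a user threshold
   (default 5 px) — artefactual laterals caused by boundary roughness are
   never longer than the radius of the parent they spring from.
4. **Traits.**  The broken-roots trait set (tips, branch points, total
   length, network area, diameter statistics, perimeter, surface area,
   volume, branching frequency, per-diameter-bin histograms) plus, in
   whole-root mode, architecture traits (row-scan root counts, depth/width,
   convex hull and solidity, lower root area, holes, angle frequencies).

## Numerical choices that matter

**Ridge rule.**  A root pixel is a ridge pixel when its distance value
strictly exceeds both neighbours of at least one opposite-direction pair
(E/W, N/S, NE/SW, NW/SE).  Even-pixel-width roots have a two-pixel distance
plateau along the centre with no strict ridge anywhere, so plateau local
maxima (≥ all eight neighbours and > at least one) are also accepted; the
resulting two-pixel-wide ridge is reduced by thinning.  We deliberately do
*not* accept mixed ≥/> comparisons pair-by-pair: on binary masks that rule
turns every per-row maximum inside rounded root ends into a ridge pixel,
producing webs of false loops that pruning cannot remove (pruning never
deletes a segment joining two branch points).  The plateau-maximum rule
keeps even-width centrelines while leaving blunt ends clean.

**Steepest ascent.**  From every ridge pixel a walk moves to the 8-neighbour
with the largest distance value until it reaches an existing skeleton pixel,
would go downhill, or revisits a pixel.  Ties take a fixed neighbour order
(E, NE, N, NW, W, SW, S, SE) for determinism; walks are capped at the
component's pixel count.  A best-first search (preferring high distance
values, coordinate tie-breaks) then guarantees exactly one skeleton
component per mask component; in practice the walks already achieve this
and the search is a no-op safety net.

**Redundant-corner collapse.**  Thinning plus spur pruning can leave a pixel
whose neighbours are already mutually connected without it: a 3-pixel
triangle corner, or a one-pixel stub riding on three consecutive collinear
path pixels.  Such pixels carry no path information but manufacture false
loops and hide real tips behind them (blunt root ends are the typical
site).  They are removed in scan order, cascaded to stability, and only
when adjacent to a junction — plain staircase bends of a simple path are
never touched.

**Pruning passes.**  Each pass evaluates all branch-to-tip segments of the
current topology and deletes every one that fails the length test; branch
pixels survive and are relabelled afterwards.  Deletions within a pass are
independent (prunable segments can share at most their kept branch
endpoints), so no within-pass ordering is needed and the result is
deterministic.  Passes repeat because merging segments across a vanished
branch point can expose new prunable tips.  Segment length is measured from
the branch pixel centre to the tip pixel centre along the path.

**Branch-point counting.**  A lateral that meets its parent at right angles
produces a cluster of 3–4 mutually adjacent pixels with ≥3 neighbours, all
marking one anatomical branch point; `count_branch_points` merges
8-connected branch-pixel clusters before counting.  At ordinary Y-shaped
junctions the cluster is a single pixel and the count equals the raw pixel
count.

**Cylinder model.**  Every skeleton pixel is a cylinder whose height is half
the summed Euclidean distance to its skeleton neighbours (heights therefore
sum exactly to the total skeleton length) and whose radius is the distance
value.  Volume is Σ h·πr², surface area Σ h·2πr, projected area Σ h·2r.
Summing per-pixel cylinders keeps volume honest when thin and thick roots
share an image; a single length × average-diameter cylinder can report
barely half the true volume in such scenes, which the heterogeneity test
and the acceptance script demonstrate explicitly.

**Diameter statistics** are unweighted over skeleton pixels (a
length-weighted variant is available through the projected-area histogram:
weighted mean diameter = Σ projected area / Σ length).  Diameter bins are
left-open/right-closed, with the first bin closed below at 0.

**Angle features.**  Each skeleton pixel's locality is the 40 × 40 px window
centred on it (20 px each side, clipped at borders); the locality
orientation is the principal axis of the skeleton coordinates in the
window, expressed as the absolute angle from vertical in [0°, 90°].  Steep
means near-vertical (gravitropic) growth: frequencies are the fractions of
pixels in [0°, 30°), [30°, 60°), [60°, 90°].  Localities with fewer than
two pixels report 0°.

**Known biases.**  The distance to the nearest background pixel *centre*
overestimates the true half-width by about half a pixel, so roots of odd
pixel width measure one pixel too wide while even widths are exact; the
weighted-diameter error is within ±1 px across the validation suite.
Skeleton path length over-estimates the length of smooth curves at
intermediate orientations by up to ~8 % (the classic 8-connected chain-code
metrication error); axis-aligned and 45° paths are exact.  Perimeter uses
the traced closed contour through boundary pixel centres (outer plus hole
contours); a one-pixel-wide appendage is traversed on both sides.

## Unit handling

Resolution is given in DPI (divided by 25.4) or pixels/mm.  All primitive
operations work in pixels; `extract_features` converts lengths by 1/s,
areas by 1/s², volumes by 1/s³ (s = px/mm), and interprets filter areas and
diameter-bin edges in mm when a resolution is present.  Without a
resolution everything is reported in pixel units.

## Synthetic validation scenes

The generator emulates flatbed scans of copper wires, the standard physical
ground-truth object for scanner-based root measurement: dark strokes
(intensity 60) on a bright background (230), gauge set AWG 40, 32, 28, 22,
16, 10 (0.08–2.59 mm) at 600 DPI, rendering to 2–61 px widths.  Strokes are
painted as the set of pixel centres within the stroke radius of the
centreline; for axis-aligned wires the centreline is lattice-aligned (odd
widths) or placed between pixel rows (even widths) so the rendered
cross-section is exactly the rounded integer width.  Ground truth models
each wire as a cylinder over its *centreline* using the rendered integer
width, so tests assert algorithm error rather than rasterization error; the
rendered round caps extend slightly beyond the centreline and their
skeleton spurs are exactly what root pruning removes.

The default validation scene holds 3–6 horizontal wires with lengths
100–160 mm (physical validation wires were ~305 mm; wires must be long
enough that a 2 px gauge is not mistaken for debris by the 8 mm² background
filter).  Every scene includes the thickest gauge, so scene totals are
dominated by well-resolved wires as in physical wire scans.  Arc-shaped
wires (circular arcs with arc-length truth) exercise curved paths and carry
the metrication bias noted above.  The corruption operator adds seeded dark
background speckles and bright in-root holes, spaced so that
size-thresholded filtering restores the clean mask exactly.

What passing these tests does **not** show: robustness to greyscale edge
gradients, scanner glare on smooth surfaces, root hairs, crossing or
overlapping roots, and textured backgrounds — real scans have all of
these.  The validation isolates the measurement algorithms from
segmentation difficulty by construction.

## Validation metrics and problem sizes

Accuracy is summarised by mean bias error (1/N)Σ(Pᵢ−Oᵢ), root-mean-square
error √(Σ(Pᵢ−Oᵢ)²/N) and the squared product-moment correlation R².  The
recovery suite and the acceptance script use 30 seeded scenes (each
roughly 500 × 4000 px at 600 DPI); operator-level oracle checks use 100–200
random masks up to 40 × 40 px, sizes at which brute-force nearest-background
search and exhaustive pruning remain exact and fast.  The published
copper-wire and simulated-root image sets can be benchmarked with
`rootquant benchmark` when downloaded; they are not bundled.

## Limitations

Global thresholding presumes high root/background contrast; complex
backgrounds need external segmentation first.  Root order classification,
per-root measurements and root-hair handling are out of scope.  Pixel-level
topology can differ from other implementations of the same pipeline on
plateau and tie configurations; the batch pruning semantics and fixed tie
orders above make this package's output deterministic and self-consistent.
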