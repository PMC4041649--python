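# Methods

## Problem and model

The tracker estimates, per video frame, the positions of three feature
points (head, center, tail) of a single earthworm in a circular dish, and
the worm's body length. The worm is modeled as a dark, elongated, elastic
blob on a lighter dish background; its centerline is recovered by binary
thinning and its length measured as geodesic distance along that
centerline. There is no motion model: temporal association is pure
nearest-endpoint matching, anchored by the observation that the tail moves
least between frames.

## Segmentation

* **ROI.** Only pixels whose centers lie inside the dish circle are
  processed. The circle may be given directly (`cx,cy,r`) or via three rim
  marks, from which the circumcircle is computed by solving the two
  perpendicular-bisector equations; marks closer to collinear than
  |det| < 1e-9·scale are rejected as degenerate.
* **Channel.** The red channel is used: with the reddish dish lighting the
  worm/background contrast is highest there. Grayscale input passes
  through (logged).
* **Threshold.** `threshold=auto` computes Otsu's threshold over the
  in-ROI pixel values only (the zeroed exterior would otherwise bias the
  histogram). Otsu's convention assigns the threshold bin to the dark
  class, so automatic thresholding uses `value <= t` for a dark object,
  while an explicit numeric threshold follows the documented strict
  `value < t` contract. A contrast-free ROI (all values equal) yields an
  empty mask rather than an all-foreground one. A uniform-intensity ROI is
  the only case where "auto" cannot produce a meaningful split.
* **Cleanup.** Connectivity is 8-connected throughout, so a one-pixel-wide
  diagonal body never fragments. Components smaller than
  `min_fragment_area` (default 50 px ≈ 2 mm² at 0.2 mm/px: far below any
  adult worm, above tape glints and dust) are removed; the largest
  remaining component is the worm. Area ties resolve to the component
  whose first raster pixel is smallest (row, col) — all tie-breaks in the
  package follow this rule so output is deterministic.

## Thinning

Hilditch's criteria decide deletion of a boundary pixel p (neighbors
p2..p9 clockwise from north):

1. 2 ≤ B(p) ≤ 6 — protects endpoints and interior pixels;
2. connectivity number 1 — p is a simple point. This is the 8-connectivity
   (Yokoi) count over the axial neighbors; a plain 0→1 transition count is
   *not* equivalent: it misses diagonal adjacency across the neighborhood
   ring and leaves two-pixel staircases undeleted.
3. the two guards (p2∧p4∧p8 ⇒ A(p2)≠1 and p2∧p4∧p6 ⇒ A(p4)≠1), which
   prevent both sides of a two-pixel-wide band from dying in one pass.

Scheduling matters as much as the criteria. Each pass (a) freezes the
pass-start image, (b) takes as candidates the pixels that are boundary
pixels *there*, in raster order, and (c) deletes a candidate only if the
criteria hold on both the frozen and the current image. Evaluating on the
frozen image prevents a pass from cascading along a band (naive immediate
deletion can consume a 2-wide diagonal staircase for its whole length in a
single pass, truncating the skeleton); the current-image re-check means
only simple points are ever removed sequentially, which preserves the
component structure exactly and avoids the pure-parallel variant's
deletion of isolated 2×2 blocks. Iteration stops when a pass deletes
nothing, so thinning is idempotent by construction.

Spur pruning removes endpoint-to-junction branches of geodesic length
below `min_spur` (default 5 px: longer than thinning artifacts, shorter
than any plausible head/tail segment at 0.2 mm/px), shortest first, one
per iteration, recomputing degrees each time. Branches ending at another
endpoint — the main body line — are never removed.

## Geodesics and feature points

The skeleton is a graph on its pixels with 8-neighbor edges weighted 1
(axial) and √2 (diagonal). Single-source distances and predecessors come
from Dijkstra's algorithm (scipy.sparse.csgraph). A literal four-neighbor
metric (diagonal = 2 axial steps) is available via `diagonal_weight=2.0`
for comparison, since on an 8-connected skeleton a strict 4-neighbor
metric would be infinite across diagonal steps.

Initialization: tail = endpoint nearest the user's seed (nearest skeleton
pixel if the skeleton is a closed loop); head = farthest finite geodesic
pixel from the tail; center = path pixel whose cumulative distance is
closest to half the tail→head total (ties to the tail side). Tracking:
tail first, to the endpoint nearest the previous tail in Euclidean pixel
distance; head to the nearest remaining endpoint (ties: larger geodesic
separation from the tail, then smallest (row, col)); the center is
re-derived geodesically rather than matched, since a matched midpoint
drifts off the body when the length changes. Frames with no segmentable
worm produce `carried_forward` records repeating the last coordinates —
explicitly flagged, never interpolated — and tracking resumes on the next
good frame. Matching breaks down when per-frame endpoint displacement
approaches the Euclidean head-tail separation, and when the body coils or
self-crosses (the skeleton stops being a two-endpoint path); both regimes
are out of scope and degrade visibly rather than silently.

## Body length and velocity

Raw geodesic path length over an 8-chain with weights (1, √2)
systematically overestimates the length of a smooth curve: for a straight
segment at angle θ the factor is cos θ + (√2−1) sin θ, which averages
8(√2−1)/π ≈ 1.0548 over orientations. `body_length` therefore multiplies
the raw path length by the standard inverse calibration π/(8(√2−1)) ≈
0.9481 (Kulpa's correction) before applying the mm-per-pixel scale;
measured on rendered worms this leaves a residual error well under 1%
(orientation averaging along a curved body keeps the per-worm factor close
to its mean). The uncorrected value remains available
(`corrected=False`); it is exact for purely axial chains by construction.

Velocities are forward differences of point coordinates at the native
frame rate — Euclidean pixel displacement × mm/px ÷ frame interval — with
no smoothing (an optional window average exists but defaults off).
Transitions touching a lost/carried frame are absent (NaN), not zero.
Summaries use the sample (n−1) standard deviation. Trajectory comparison
reports Pearson r between raw coordinate series per axis and the mean ±
sd of per-transition velocity differences; r for a constant pair of
identical series is defined as 1, and undefined (NaN) otherwise.

The package carries published body-length summaries for the two study
species (an epigeic and a polyhumic-endogeic earthworm) as reference
constants; the stretch range max − min computed from them (75.05 mm and
59.29 mm) is the in-package arithmetic cross-check of the ~1.5× elastic
stretch.

## Synthetic data

The generator emulates the recording conditions: 640×480 8-bit frames,
0.2 mm/px, 1 s intervals, a dish of 85 mm inner diameter centered in the
frame, light dish interior (red ≈ 210) on black exterior, dark worm
(red ≈ 60) with deliberately weaker green/blue contrast, and Poisson speck
noise whose disk areas stay below the 50 px fragment threshold. Speck
positions are drawn relative to the arena center so integer-pixel arena
translations translate frames exactly — this is what makes the
translation-equivariance check exact rather than approximate.

The worm is a disk-swept centerline of half-width `half_width` laid
backward from the head along an arc-length-parameterized guide path; its
arc length is L(t) = L₀(1 + A sin(2πt/T)) with A ≤ 0.5 (the 1.5× elastic
limit). The head advances at constant speed; the true center is the
arc-length midpoint. Poses whose body (plus half-width margin) would leave
the arena raise an error — enforced, not clipped. Rendering computes exact
point-to-segment distances (evaluated in per-segment windows for speed),
so the stamped pixel set equals the brute-force disk-union oracle
bit-for-bit.

Defaults describe an adult worm: rest length 160 mm, stretch amplitude
0.2, period 30 s, head speed 2 mm/s, half-width 2.5 mm. A 160 mm worm in
an 85 mm dish necessarily coils, so the default crawl path is an inward
Archimedean spiral (36→12 mm, 9 mm ring gap) whose gap keeps body rings
from self-touching. The `coil` preset follows a self-crossing loop and is
the labeled failure scenario. What the generator does **not** emulate:
motion blur, shadows and uneven illumination, dish-wall contact, partial
occlusion, true peristaltic waves (stretch is global, not segmental), and
JPEG compression artifacts. Passing the synthetic benchmarks therefore
demonstrates correctness of the geometry and bookkeeping, not robustness
to real-video nuisance factors.

## Benchmark problem sizes

The validation experiments (shared by the test suite and
`scripts/acceptance.py`) use thin, juvenile-scale worms — half-width
0.3–0.5 mm (≥ 3 px wide rendered), rest lengths 30–60 mm — because feature
point accuracy is assessed against the true body *tip*, and a skeleton
endpoint sits roughly one half-width short of the tip of the rounded body
cap; thin bodies keep that geometric offset inside the pixel-level error
budget. Sequence-level settings are chosen so each scenario stays inside
the matcher's stated working regime:

* tracking stability: rest 40 mm, A = 0.1, T = 40 s, speed 1.2 mm/s —
  maximum endpoint displacement = speed + L₀·A·2π/T ≈ 1.8 mm/s, i.e.
  ≤ 10 px per 1 s frame;
* speed recovery: speed 2.0 mm/s, A = 0.15, T = 25 s, 100 frames;
* stretch-ratio recovery: A = 0.5, T = 40 s, 90 frames — the 1 s sampling
  grid hits the sine's peak and trough exactly, and the true max/min
  length ratio is 1.5/0.5 = 3;
* thinning invariants: 200 random multi-disk blob masks at 64×64;
* oracle equivalence: exhaustive 256-way Otsu search, BFS flood-fill
  labeling, and queue-free repeated-relaxation shortest paths on ≤ 200 px
  skeletons.

## Known limitations

* Coiled, looped, or self-crossing bodies are not resolved (no topological
  disambiguation); the tracker falls back to farthest-point extraction
  when endpoints vanish, which is best-effort only.
* Head/tail disambiguation is purely positional; a worm that reverses
  within one frame interval faster than half its end-to-end separation can
  swap labels.
* The Otsu threshold assumes a bimodal in-dish histogram; strong
  illumination gradients would need background modeling, which is out of
  scope.
* Body length is measured along the skeleton, which ends about one
  half-width short of each true body tip; for wide adult worms this
  truncation partially offsets the (corrected) chain-length metrication,
  and lengths carry a residual bias on the order of 1–2%.
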