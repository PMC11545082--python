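# Methods

This note records the models, parameter choices and numerical decisions
behind `cagepose`, and what the synthetic benchmark does and does not
demonstrate about real farm imagery.

## Frame model and storage

A frame is a registered pair: 8-bit 3-channel color and 16-bit
single-channel depth at 640×480. Depth is interpreted as millimetres,
with 0 reserved for "no reading" — sensor dropout, the black registration
borders (50 columns on each side, a by-product of depth/color
registration), and regions warped in from outside the frame. Other frame
sizes are accepted, but the pixel-denominated defaults (ROI, margins,
Hough lengths) are tuned to 640×480 and are the caller's responsibility
to rescale.

Merged storage is a 16-bit 4-channel PNG: channels 0–2 hold R, G, B
scaled 8→16 bit by ×257 (0→0, 255→65535, inverted exactly by rounding
division), channel 3 holds depth verbatim. The mainstream Python imaging
stacks cannot round-trip 16-bit RGBA PNGs losslessly, so the package
carries a small codec for exactly this layout (non-interlaced, bit depth
16, color type 6; encode with filter 0, decode all five scanline
filters). Everything else is rejected with an error naming the offense.

## Roll correction

The estimator assumes the trough edge is the longest near-horizontal
straight structure in the preset ROI (x 25–615, y 80–300). The chain is
grayscale (ITU-R 601 luma) → y-direction 3×3 Sobel (reflective borders)
→ 3×3 median (reflective) → threshold 100 → probabilistic Hough →
redraw all segments on a black canvas → second Hough → longest segment.
The double pass exists because a single pass fragments one physical edge
into collinear pieces; the redraw-and-reextract step fuses them so
"longest" refers to the whole edge. Segments steeper than 45° are
treated as misses (the trough is near-horizontal by construction of the
rig), as is any frame where either pass finds nothing; unfound tilt
means the frame passes through uncorrected.

Two numerical choices matter:

* **Angular resolution 0.25°** (not the more conventional 1°). The
  probabilistic Hough walks pixels along the accumulator's quantized
  direction, so segment endpoints — and any angle derived from them —
  snap toward the angular grid. At 1° the recovered roll showed a mean
  absolute error of ≈0.23° with worst cases above 0.5°; at 0.25° the MAE
  drops to ≈0.1° for endpoint angles, at negligible cost.
* **Support-fit inclination.** The reported angle is not taken from the
  longest segment's endpoints but from a total-least-squares (principal
  axis) fit of the canvas pixels within 3 px of that segment's line.
  The segment selects *which* edge; its support measures the angle at
  sub-quantization accuracy and is robust to the segment covering only
  part of the edge. With this refinement the roll-recovery MAE on
  synthetic scenes is ≈0.05°.

The correction matrix is the standard rotation-about-a-point affine for
−θ (positive θ = scene tilted counterclockwise as displayed; correction
rotates clockwise). The rotation center defaults to the image center
(320, 240), which also reproduces the published worked example for this
method (0.978° → translation entries 4.144, −5.428 within 0.01; their
angle is printed rounded). Color is warped bilinearly; depth uses
nearest-neighbour so no depth values are invented at object boundaries —
a warp by a small angle moves well under 2 % of the nonzero-depth
histogram mass.

## Trough location and key area

Both locators reduce the problem to "find the longest vertical run of
flagged rows", encoded as a dotted vertical line at the analysed columns'
midpoint and extracted with a probabilistic Hough pass (threshold 10,
min length 20, gap 5, 1° step — the dotted-line geometry does not need
fine angles). Only columns 50…width−50 are analysed, excluding the
registration borders.

* **Variance method**: a row is flagged when its depth variance —
  computed over nonzero pixels only, so dropout never poisons a flat row
  — is below 400 mm². The default suits scenes where genuine background
  texture has a depth spread an order of magnitude above the sensor
  noise (σ ≈ 5 mm → variance 25 mm²); it is exposed in config for other
  regimes.
* **Keypoint-sparsity method**: an interest-point detector runs on the
  depth map rendered to 8 bits (min–max over nonzero depth); a row is
  marked if it or an immediate neighbour carries a keypoint, and the
  *unmarked* rows trace the trough — the flat band attracts no
  keypoints. The detector is pluggable (any callable 8-bit image →
  (row, col) array). The default is a determinant-of-Hessian blob
  detector, the same response family as SURF's interest operator, with
  the SURF-convention 8-bit threshold (default 400) rescaled by
  1/(2·255²) to the unit-intensity scale; the factor was calibrated once
  so the default density matches a SURF detector at its default
  threshold on textured depth renderings.

Ties for the longest segment go to the first in scan order, making both
locators deterministic (the Hough's internal sampling is seeded).

The key area starts at the trough's bottom row, spans the frame minus a
25-px margin per side (590 px at 640 wide — the margin is kept
independent of the 50-column analysis border; the two constants come
from different stages of the original protocol), and is
`max(1, round(k1·l_AB))` tall, clipped to the image bottom. Scaling the
height by the trough height makes the search area track the camera–cage
distance: closer camera, taller trough, taller key area.

## Posture identification

For column *c*, the reference depth `d_c` is read at the trough band's
middle row, `(row_top + row_bottom) // 2`. A key-area pixel with depth
`d′` is foreground iff `d_c + k2 < d′ < d_c + k3`, both inequalities
strict, evaluated per column. Columns whose reference reads 0 are
skipped entirely (the rule is undefined there), and zero-depth pixels
are never foreground. The per-column reference is the point of the
method: it absorbs the depth gradient across the frame caused by
perspective and yaw without any extrinsic calibration.

Cleanup and filtering, in order:

1. morphological opening then closing with a 3×3 elliptical footprint,
   then a 3×3 median — removes speckle without eroding bird-sized blobs
   by more than a pixel;
2. column fill: erase every column with `N_c ≤ H_roi / k4` foreground
   pixels (strict survival). With `k4 = 2` a column must be more than
   half full — legs are short, bodies are tall;
3. fragment merging: while any two connected components' edge contours
   come within `merge_gap_px` (20 px, strict), connect the closest pair
   of contour points with a 1-px line and re-extract. Contour distance,
   not centroid distance: two halves of one bird can be near-touching
   while their centroids sit 100 px apart. Pairs are processed in
   ascending distance; the loop is idempotent by construction;
4. box extraction: components below `min_contour_area_px` (50 px², a
   configurable floor for "too small to be a bird part") are dropped;
   surviving bounding boxes are kept iff `W/H > k5` (strict). Lying
   birds are flat-wide; pillars are tall-thin.

The column-fill and aspect tests are read as `N_c > H_roi / k4` and
`W_rect / H_rect > k5`: with `k4 = 2` a product reading `N_c > H_roi·k4`
is unsatisfiable (`N_c ≤ H_roi` always), so the divisor reading is the
only consistent one, and it matches the tests' described purpose.
Overlapping surviving boxes are all emitted; the pipeline does not
arbitrate between them.

`detect_lying` chains all stages; a frame whose trough cannot be found
yields an empty detection list with a logged skip, not an error, since a
batch run must survive bad frames.

## Synthetic scenes

The generator emulates the structure the pipeline depends on, not the
appearance of a broiler house:

* background plane at 1100 mm with smooth undulation (σ = 50 mm,
  ≈20 px correlation) plus ~300 hard bumps 60–140 mm behind the plane —
  enough texture that background rows exceed the variance threshold by
  an order of magnitude and attract dense keypoints;
* trough band (rows 180–260) at 600 mm, exactly flat before sensor
  noise, with sharp depth steps and a strong color step at its edges;
* lying birds: filled ellipses with half-axes 52×20 px (per-bird scale
  jitter 0.9–1.1) directly beneath the trough, at a depth offset drawn
  uniformly from (80, 220) mm — strictly inside the default (k2, k3)
  band, centred on 150 mm;
* standing birds: two 5×16 px leg strokes (16 < 48/2, so they cannot
  survive the column-fill test); an optional flag renders part of a
  small bird's body into the key area to reproduce the known
  small-breed failure mode where standing birds get flagged;
* pillars: 24-px-wide full-height rectangles at trough + 150 mm — they
  pass segmentation and column fill and must be rejected by aspect
  ratio alone;
* camera/sensor model: whole-scene roll (default 1°, the carriage-shake
  scale), additive Gaussian depth noise (σ = 5 mm), Bernoulli dropout
  (2 %), 50-column black borders, mild color noise. The color channel is
  a dim depth-shaded rendering (peak intensity 90/255): sufficient for
  the edge-based roll estimator, deliberately insufficient for
  color-only detection. The noise model is a coarse stand-in for a
  structured-light sensor, not a sensor simulation.

Ground-truth boxes are recorded in deskewed coordinates — the frame the
correction stage recovers — so end-to-end scores include any residual
correction error. Everything is deterministic given the seed; dataset
frames derive per-frame seeds from the master seed.

What passing the synthetic benchmark shows: the geometry and filtering
chain is implemented correctly, each filter rejects exactly the
distractor class it targets, and the stages compose under roll, noise
and dropout. What it does not show: performance under real feather
texture, bird–bird occlusion, trough clutter, or depth artifacts beyond
iid noise and dropout — the published farm-scale scores are not
reproducible without the original footage, and the benchmark's near-
perfect scores should not be read as a claim about farms.

## Evaluation choices

Greedy one-to-one matching by descending IoU (ties: detection index,
then annotation index). The task defines no natural negatives, so a
frame with neither lying annotations nor detections contributes one
frame-level true negative; accuracy is otherwise undefined. Undefined
precision/recall ratios report 0 with a warning rather than raising,
since a tuning sweep routinely visits degenerate corners. The grid
search enumerates exhaustively (no optimizer), skips infeasible corners
such as k2 ≥ k3, precomputes the parameter-independent stages
(correction, trough) once per frame, and breaks F1 ties toward the first
combination in grid order. The daily status rule flags `lying fraction
≥ 0.5` as abnormal — the boundary counts as abnormal — with the lying
fraction computed over uniformly sampled observations.

## Problem sizes

The shipped benchmark and acceptance script use 100 end-to-end frames,
50 roll-recovery scenes, a 12-point (k2, k3) grid over 8 frames, 200
oracle-comparison images at 64×48, and 50 format round-trip frames —
sizes chosen to exercise every stage at full 640×480 frame geometry
while keeping a desk-scale run in tens of seconds.

## Known limitations

* Only roll is corrected; pitch and yaw are absorbed by the per-column
  dynamic threshold, not rectified.
* A bird fully occluded by the trough is undetectable in principle.
* Resting and sick birds cannot be distinguished from posture alone; the
  status rule is an attention filter, not a diagnosis.
* The detector cannot separate two lying birds closer than the 20-px
  merge gap; they fuse into one box.
* Frame-level true negatives make accuracy depend on the fraction of
  empty frames in a dataset; precision/recall/F1 are the comparable
  quantities across datasets.
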