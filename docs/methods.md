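# Methods

## Optical model

The camera is modelled as a thin lens in its far-field regime: magnification
is taken as `f/u` rather than the exact conjugate `f/(u−f)`. At the working
distances (120–300 mm) with a ~4 mm focal length the two differ by under 2%,
and the far-field form is the one that makes the pixel/mm bookkeeping
consistent with the fiducial-distance relation `u = f·D/(ø·p)`; the exact
form is deliberately not used anywhere.

Pixel pitch comes from `p = 2·f·tan(θ/2)/W_m` along one axis (CMOS cells are
square). Intrinsics can be built from either the view angle or the pitch;
whichever is given, the other is derived. For the bundled HTC Desire 820
profile the authoritative pair is (f = 3.81 mm, p = 2.377 µm): the view
angle implied by them (~105.6° horizontal) is wider than plausible for a
phone and is therefore treated as informational only.

Phones usually record at a lower resolution than the native sensor. The
effective pitch at capture resolution is `p × (sensor_px / capture_px)`
along the same axis; all pixel→mm conversions use the effective pitch, so
measurements are consistent whether the profile describes native or binned
capture. All distances are lens-to-plane along the optical axis; image
coordinates are 0-based, origin top-left, x rightward, y downward.

## Segmentation

RGB is converted to CIE L\*a\*b\* (sRGB primaries, D65 white) and the b\*
channel thresholded by Otsu's method. b\* is affinely quantised to 8 bits
(b\*+128, clipped) before building the 256-bin histogram, so the threshold
is reproducible and reported on that scale; foreground is the strict
high-b\* class. No white-balance or shadow correction is applied — working
in b\* already makes the split approximately luminance-invariant, which the
shading-robustness tests confirm (mask IoU moves by <0.02 under 0.5–1.0×
intensity scaling).

Cleaning order: (1) components below `min_area_px` (default 0.1% of image
pixels) are removed; (2) each component is opened with a Euclidean disk of
radius `stalk_width_px/2` (default width 2% of image width), which erases
peduncle-like protrusions; only the largest opened piece per component is
kept, and a component thinner than a stalk everywhere vanishes; (3) a final
1-px-radius dilation smooths the outline. The opening is computed with two
exact Euclidean distance transforms, equivalent to erode/dilate with a disk
structuring element but fast at 1920×1080 for large radii. Only external
contours are extracted, so specular holes inside a fruit cannot fragment it.
The defaults encode only the prior that fruit are much larger than stalks
and debris; both are configuration-overridable (a 10 mm fiducial at 300 mm,
for instance, needs a lower area floor).

### Dilation compensation

The final dilation is an outline-smoothing step, but it adds exactly one
pixel of radius — about +2 px on every fitted diameter and bounding-box
side. Measurement functions therefore subtract `edge_compensation_px`
(default 2.0) from the fiducial's fitted minor axis and the fruit's bounding
box before converting to millimetres. This is a calibration of a known,
deterministic morphological bias, not a tuning knob: without it, distance
estimates carry a systematic ~2/ø relative error (≈4% for a 40 mm circle at
300 mm). The anti-aliased boundary itself is unbiased to within ~±0.3 px
because the Otsu threshold lands mid-blend.

## Identification and quality gates

Each cleaned component gets a moment-based ellipse (axis lengths from second
central moments, the standard regionprops definition — equivalent to a
least-squares ellipse fit for solid regions). Eccentricity is the true
ellipse eccentricity `ε = √(1−(b/a)²)`: 0 for a circle, → 1 for a line.

The reference circle is the component with ε at or below the tilt gate
(default 0.3) whose minor-axis diameter is closest to the diameter predicted
at the middle of the working range; the fruit is the largest remaining
component by area. The minor axis is used for the distance estimate because
operator tilt mostly forms about the phone's long axis and foreshortens one
axis only; for an untilted frame minor ≈ major. With one candidate per
scene the rule is exact; when a spherical fruit and the fiducial subtend
similar diameters at extreme distances the size-matching rule can in
principle misassign — single-fruit scenes with a mid-range stand-off (the
intended use) are unambiguous.

Gates, all configuration-exposed:

* **tilt**: reference ε ≤ 0.3. Under an orthographic tilt model a circle
  tilted by φ images with ε = sin φ, so the gate corresponds to ≈17° and
  comfortably rejects ≥20° (ε ≥ 0.34). The commonly quoted 14° pairing
  gives ε = 0.242 orthographically; the gate is applied to the measured ε,
  never to a reconstructed angle. Because candidates are filtered by the
  gate, a tilted fiducial surfaces as "no reference"; the pipeline then
  checks for a fiducial-sized over-gate component and reports the rejection
  as tilt rather than absence.
* **distance**: 120 ≤ u ≤ 300 mm.
* **contact**: fruit and fiducial components must not be 8-adjacent. A full
  overlap merges both into one blob before labelling; a single component
  far larger than the expected fiducial and too elongated to be the circle
  is reported as contact. (A lone oversized fruit with the fiducial out of
  frame would also trigger this branch; the record is rejected either way.)

Fruit shape class drives the allometry: ε > 0.35 → "ellipsoid"
(mango/avocado), otherwise "sphere" (apple/citrus/mandarin). The gate sits
between noisy spheres (ε ≲ 0.2) and mango-like outlines (ε ≳ 0.5); ties go
to sphere. The class can be forced per batch.

## Sizing and depth correction

Fruit image length/width are the axis-aligned bounding-box height/width (the
fruit's long axis aligns with the board's long axis in normal use), less the
dilation compensation. The fruit perimeter lies half a thickness in front of
the board, so with `k = p·W_i/f`:

    W_0 = u·k,    T_n = c·W_n,    W_{n+1} = (u − T_n/2)·k

iterated until |ΔW| < `tol_mm` (default 0.1 mm, below the ~1.2 mm caliper
repeatability; `max_iterations` 20). The update is affine, so the error
contracts geometrically with ratio `c·k/2` and alternates in sign around the
fixed point `W* = u·k/(1 + c·k/2)`; the tests verify both the contraction
ratio and agreement with `W*` to 1e-6 mm. At the representative operating
geometry (80 mm mango at 200 mm) the width stabilises to 0.1 mm within five
passes; at the close end of the working range the contraction ratio reaches
~0.4 and up to ~9 passes are needed — still milliseconds. A convergence
error is only possible when `c·k/2 ≥ 1`, i.e. geometrically absurd inputs.
Length is corrected with the same final `(u − T_r/2)`; both the board
distance and the corrected distance are recorded.

Allometric slopes: ellipsoid `c = 0.88` (pooled mango regression, also
applied to avocado), sphere `c = 1.0`. Per-cultivar mango alternatives ship
as a documented table (Honey Gold 0.82, KP 0.87, Calypso 0.90, Keitt 0.82,
pooled 0.88) and any slope in [0, 1.2] can be configured; `c = 0` reduces to
the uncorrected thin-lens values in a single pass.

Survey planning uses `n = ⌈(t·SD/e)²⌉` with t = 1.96 — the ceiling ensures
the target precision is met (SD 18.7/14.2 mm at e = 5 mm give 54 and 31).

## Synthetic scenes

The renderer draws, at the camera's capture resolution under the same
pinhole constants the pipeline uses: a blue A4 board (297×210 mm) at
distance u; a yellow circle of known D in the board plane; and the fruit as
the projected mid-cross-section ellipse of an L×W×T ellipsoid at depth
(u − T/2) — exactly the perimeter plane the sizing model assumes, so full
ray-traced silhouettes are unnecessary. Camera pitch is orthographic:
vertical extents scale by cos(tilt), giving the circle an eccentricity of
sin(tilt). Degradations: multiplicative shading left of the fruit centre,
Gaussian boundary blur (σ = 2 px emulates the ~4 px yellow/blue blend seen
at 200 mm on a real phone), and seeded additive pixel noise. Edges get a
1-px linear coverage blend; ground-truth masks are hard pixel-centre
classifications partitioning the frame into board/circle/fruit/outside.

Default colours: board (30,60,200), circle (240,220,30), fruit presets
green/red/yellow. The margin outside the board defaults to a darker blue —
the operator fills the frame with the board, and whatever margin remains
must sit on the blue side of the b\* split; a grey or black margin would be
classified foreground by a two-class global threshold. That is also the
renderer's main departure from reality: real canopy backgrounds (green
foliage has positive b\*) are not modelled, so passing tests demonstrate
correctness of the geometry and of the segmentation logic on
board-dominated frames, not robustness to arbitrary backgrounds. Likewise
unmodelled: specular highlights beyond uniform noise, perspective (rather
than orthographic) tilt distortion, lens distortion, and real sensor colour
rendering.

One integer seed drives all stochastic settings; a fixed seed re-renders a
bit-identical image set.

## Numerical and format choices

* Eccentricity uses the square-root form; the linear form `1−(b/a)²` is
  inconsistent with ε = 0 at a = b and with a 0.3 circle gate.
* Otsu threshold equals the exhaustive between-class-variance argmax over
  the 256 quantised levels (property-tested); first maximum wins ties.
* Boundary classification is strict: foreground is b\*₈ > threshold; the
  fruit-class gate assigns the boundary value to "sphere".
* CSV: comma-separated, UTF-8, header row, "." decimal, 3-decimal fixed
  floats, `true`/`false` booleans, empty strings for missing GPS and for
  size fields of rejected records. Re-running a batch produces a
  byte-identical file; timestamps come from EXIF only (never wall clock).
* Degenerate inputs raise typed errors (`DegenerateInputError`,
  `NoThresholdError`, …) at the library level; the batch pipeline converts
  every per-image failure into a rejection row instead of aborting.

## Validation problem sizes

The test suite and the acceptance script render at the phone's working
resolution (1920×1080) where measurement precision is asserted (end-to-end
grid: 9 stand-offs × 3 fruit sizes, noiseless; fiducial-size sweep:
3 diameters × 9 stand-offs × 3 noise seeds under σ=2 px blur and σ=8 pixel
noise), and at a 960×540 binned profile for unit tests where geometry, not
precision, is under test. Noiseless end-to-end recovery is ~0.4% worst-case
for size and ~0.2% for distance, against the 2%/1% assertions; the residual
is rasterisation plus the anti-aliased-boundary/threshold interaction.

## Known limitations

Single fruit per frame; occlusion and fruit–fiducial contact are rejected,
not resolved. No perspective rectification of tilted boards — tilt is gated
out instead. The allometric thickness is a population-level model: an
individual fruit deviating from `T = c·W` biases its own depth correction
proportionally. Real-image colour calibration beyond sRGB assumptions, and
learning-based segmentation, are out of scope.
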