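# Methods

This note documents the models, parameter choices, numerical decisions and
known limitations of the stereopupil pipeline. Everything quantitative
stated here is computed by the test suite or by `scripts/acceptance.py`.

## Coordinate and ellipse conventions

Image coordinates are 0-based with the origin at the centre of the
top-left pixel, x rightward, y downward; all pixel quantities are
sub-pixel valued. Ellipse angles are degrees, counterclockwise from +x to
the major axis, normalised to [0, 180); the convention is ours — the
upstream tools this mirrors do not state one. `fit_ellipse` returns conic
semi-axes, while `PupilFit` stores full axis lengths so that the reported
pupil diameter equals the major axis. The fit itself is the direct
least-squares conic fit provided by `skimage.measure.EllipseModel`
(Halir–Flusser), wrapped with axis ordering and angle normalisation; the
test oracle for it is parametric resampling, not a second library.

## Baseline dark-pupil detector

Pipeline: intensity threshold → morphological open+close (disk radius 2 px)
→ connected-component selection → sub-pixel boundary → ellipse fit.

* **Threshold.** A fixed "darkest fraction" percentile is scale-fragile:
  when the pupil covers less than the percentile, the anchor lands in the
  iris and the mask merges pupil and iris. We therefore use the darkest
  `threshold_percentile` (default 0.1%) intensity only as a *dark anchor*
  — under the dark-pupil assumption it lies inside the pupil whenever the
  pupil covers ≥0.1% of the searched region — and threshold at the
  midpoint between that anchor and the region median. With an ROI over the
  eye (the intended use at full sensor resolution) the assumption is mild.
* **Gates.** Components must have area in `[min_area, max_area]`
  (default 150 px² to 40% of the region) and fitted axis ratio at least
  `min_axis_ratio` (default 0.2). Among equal-area candidates the darkest
  interior wins (dark-pupil tie-break). A uniform image yields no valid
  component and an invalid fit with outline confidence 0; detection never
  raises on a well-formed image.
* **Boundary.** The reported ellipse is fitted not to the binary mask but
  to the `find_contours` iso-contour at the midpoint between the
  component's interior mean and its surrounding-ring mean. On anti-aliased
  edges this interpolates the true edge crossing, which is what makes
  noiseless axis recovery better than 1% across pupil sizes of 40–300 px
  (verified in the test suite, typically ≲0.15%).

## Fit-confidence metrics

* **Outline confidence** = `clip((μ_out − μ_in)/T_sat, 0, 1)`, with band
  means sampled along ellipse normals at offsets 1…`band_px` px
  (`band_px = max(2, 5% of the major axis)` in the detector) by bilinear
  interpolation. The exact formula of the cited upstream confidence is not
  published, so the saturation constant is ours: `T_sat = 25` gray levels
  makes a clean dark-pupil boundary (pupil ≈30, iris ≈140) saturate at
  exactly 1, which the downstream strictly-below-1 filter requires.
  Offsets start 1 px off the boundary so anti-aliased edge pixels do not
  dilute either band.
* **Axis ratio** = b/a ∈ (0, 1].
* **Angular edge spread** bins support-point angles about the centre into
  `n_bins = 8` sectors (octants — the coarsest spread-sensitive choice)
  and reports the occupied fraction.
* **General confidence** (used when a detector has no native confidence)
  is the arithmetic mean of the three.
* Circumference is recorded via Ramanujan's first perimeter approximation
  (no formula is prescribed by the CSV schema it mirrors).

## Camera model and calibration

Standard pinhole model with radial/tangential (Brown–Conrady) distortion
`C = (k₁, k₂, p₁, p₂, k₃)`. Undistortion inverts the model by fixed-point
iteration (≤20 iterations, tolerance 10⁻⁸ in normalised units); with zero
coefficients it is exactly the identity, and round trips are below
10⁻⁶ px for normalised radii < 0.5.

Intrinsic calibration is Zhang's method, written against
numpy/scipy because no OpenCV build is a dependency of this package:

1. per-view plane homographies by normalised DLT;
2. closed-form focal initialisation from the two orthonormality
   constraints per homography, with the principal point fixed at the image
   centre for the initial step (the general closed form is
   ill-conditioned at this rig's ~8° field of view);
3. joint refinement of `(f_x, f_y, c_x, c_y, C)` and all per-view poses by
   sparse Levenberg–Marquardt-style least squares
   (`scipy.optimize.least_squares` with an explicit Jacobian sparsity
   pattern), tolerances 10⁻¹⁴.

On noiseless synthetic views all parameters are recovered to machine
precision; with 0.1 px corner noise the residual RMSE equals the injected
noise floor (≈0.14 px per point). Reprojection errors are per-point
Euclidean: RMSE = √(mean d²), MAE = mean d. We make no attempt to
reproduce a per-coordinate MAE convention; the upstream report of
RMSE 0.341 px alongside MAE 0.041 px is inconsistent with any single
residual convention, so only the RMSE is used as a quality bar.
Verification re-estimates per-view poses by PnP with frozen `K, C`,
giving an unbiased (held-out) MAE that exceeds the in-sample MAE in
expectation.

Stereo calibration fixes both cameras' intrinsics, initialises the
relative pose from quaternion-averaged per-view pose differences, and
jointly refines it with the pattern poses against both cameras'
reprojections. `M₁ = K₁[I|0]` (the main camera is the world origin — we
read the upstream description's swapped R/T wording geometrically), and
`M₂ = K₂[R|T]`.

Calibration state persists as a YAML document (pattern attributes, both
cameras' parameters and errors, stereo `R` row-major, `T` in mm, error
measures, creation timestamp); floats are written at full repr precision
so save/load round trips are bit-exact.

## Triangulation and the absolute diameter

Corresponding points are undistorted, then triangulated by the
homogeneous linear least-squares (DLT) intersection: the smallest-singular
vector of the 4×4 system built from `M₁, M₂`. The homogeneous result
converts to Cartesian with `ω = W_H` if `W_H ≠ 0`, else `ω = 1`. Rows of
the DLT system are deliberately *not* re-normalised: row scaling was
measured to inflate depth noise several-fold off the rig's mid-plane,
whereas the plain system matches the closed-form two-ray midpoint oracle
to 10⁻⁸ mm on noiseless input and matches the analytic depth-noise law
`σ_z ≈ √2 (z/f) σ_px z/(b)` under noise. Near-parallel ray pairs
(below 10⁻⁸ rad, e.g. a zero-baseline rig) raise a degenerate-input error.

The diameter of a frame pair is the Euclidean distance of the two
triangulated major-axis endpoints. One subtlety is the endpoint
*direction*: a fronto-parallel pupil images as a near-circle, whose
fitted axis angle is noise — if each camera extracts endpoints along its
own fitted angle, the two cameras pick different rim points and the
mismatched rays miss each other, which the shallow triangulation geometry
amplifies into gross depth errors (tens of mm for a 5 mm disk in our
end-to-end test). Both cameras therefore extract the centre chord along a
single shared direction: the major-axis angle of the more elliptical of
the two fits. For distinctly elliptical fits this is exactly the
major-axis endpoint pair (the rig has no relative roll); for
near-circular fits it is the well-conditioned choice. Frames where either
detection is invalid produce a missing measurement (empty CSV field),
never an exception, and no reliability threshold is applied at this
stage — screening belongs to pre-processing.

Stereo frames are paired strictly by hardware frame count (timestamps are
recorded but never used for pairing); duplicated counts in a stream are
treated as corruption.

## Two-step pre-processing

1. **Confidence filter**: remove records whose outline confidence
   (minimum over the two cameras; clamped to [0, 1] and rounded to six
   decimals so CSV round trips cannot flip the comparison) is strictly
   below 1. Blink spans are exactly these removed spans; no separate
   blink detector exists.
2. **Axis-ratio filter**: on records surviving step 1, compute
   `Δr = ratio_main − ratio_secondary` and remove records farther than
   `k·1.4826·MAD` (default k = 3) from the median; if MAD = 0, remove
   records with `Δr ≠ median`. "Strong outlier" is not quantified
   upstream; median ± 3 robust SD is our choice. The outlier statistics
   pool *all* confidence-surviving records (including previously
   axis-flagged ones), which makes the two-step procedure exactly
   idempotent. A 3σ rule necessarily removes ≈0.27% of clean Gaussian
   samples; this is visible in the clean-kept rate (≥99%) and is the
   price of the blunt robust threshold.

Filters are non-destructive (flags plus removal reason; raw values kept).
Derived statistics: invalid data rate = 100·removed/total; steady-state
mean over the trailing 5 s window of surviving samples; linear
interpolation of removed spans up to a caller-set maximum gap, longer
spans staying missing. Axis-ratio statistics are computed per series, not
pooled across trials.

## Acquisition arithmetic and I/O

The hardware trigger is a 50%-duty square wave; each rising edge triggers
one frame, so pulse width (µs) = frame interval / 2 — the documented
pairing of a 10 ms interval with `<Tx100x5000>` forces this duty
convention. MB means 10⁶ bytes (decimal): a 2048×1536 8-bit frame is
3.15 MB, and 120 fps needs 377.49 MB/s per camera (755 MB/s stereo).
Measurement CSVs have a fixed 21-column header (filename/timestamp
identity, per-camera ellipse parameters, diameters, circumference,
confidences, physical diameter); columns are keyed by name on read,
floats written at 6 decimals, missing values as empty fields. The file
camera orders frames by the trailing integer in the filename stem
(numeric, so `img_2` precedes `img_10`) and reports unparsable names
without aborting the stream.

## The synthetic generators

`SimConfig` defaults *are* the reference study conditions: 2048×1536 px
cameras with f_x = f_y = 14493 px (a 50 mm lens on a 3.45 µm-pixel
sensor), zero distortion, 75 mm baseline, 8° vergence, 700 mm working
distance (≈0.048 mm/px object-space scale); endpoint noise 0.05 px
(sub-pixel averaging of an ellipse fit over many boundary pixels); blink
fraction 0.5% with confidence drawn U(0.2, 0.8) and a 0.5 mm diameter
corruption; matching-artifact fraction 2% with a 0.2 mm diameter offset at
confidence 1; a 5 mm reference object. Corner noise for calibration
experiments is 0.1 px (single camera) and 0.02 px (stereo validation),
applied per coordinate.

The eye renderer draws an anti-aliased dark pupil ellipse on an iris disk
on a sclera background (grays 30/140/200) with additive Gaussian pixel
noise; it emulates the *photometric class* of NIR dark-pupil images, not
eyes: no iris texture, corneal glints, eyelids or gaze-dependent
foreshortening. Blink artifacts are statistical (confidence + diameter
corruption), not rendered eyelids. Passing tests therefore demonstrate
the geometry, calibration, triangulation and filtering logic — not
detector robustness on real eye images.

True image ellipses of the reference disk are obtained by densely
sampling the world circle, projecting through the full camera model and
refitting (the perspective image of a circle is an ellipse, so this is
exact to numerics). Artifact diameter offsets are calibrated at setup
time by probing the rig's diameter-per-pixel-shift slope, so "a 0.2 mm
mismatch" means 0.2 mm of *triangulated* error by construction. All
generators are pure functions of (config, seed).

Chessboard pose sampling: tilt magnitude U(0°, 30°) about a uniformly
random in-plane axis, free roll U(0°, 360°), pattern centre laterally
within the shared field and depth U(1.0, 1.3)× working distance, with
rejection sampling until every corner is at least 30 px inside every
requested camera's frame. A geometric consequence of the 8° vergence is
worth noting: the two cameras' shared field at the working distance is
only ≈75 mm wide, narrower than the 80 mm inner-corner span of a
landscape 9×6, 10 mm board, so fully-visible stereo poses are portrait
and/or tilted and/or beyond the working distance.

## Problem sizes used by tests and the acceptance script

Unit and property tests run the full-resolution camera *geometry*
(corner sets, fits, triangulation) but render images at reduced sizes
(256–800 px frames, f scaled accordingly) where actual pixels are needed;
calibrations use 10–30 views; the reference-object experiment uses 3000
frames. These sizes were chosen so the whole suite completes in about
two minutes while keeping every estimate's noise floor far below the
asserted tolerances.

## Known limitations

* The triangulated pattern-square validation is dominated by depth noise:
  `σ_z ≈ (z²/(f·b))·√2·σ_px ≈ 0.02 mm` at 0.02 px corner noise, which
  couples into adjacent-corner distances through the out-of-plane
  component of the corner direction on tilted boards. With the tilt span
  above, the measured square-size MAE is ≈0.004–0.005 mm; near
  fronto-parallel validation views (geometrically impossible for a fully
  visible stereo board on this rig, see above) would be needed to reach
  the ≈0.003 mm regime. The single-number "calibration accuracy" of a
  stereo rig is thus strongly view-geometry dependent.
* The baseline detector is intended for clean laboratory NIR images (or
  the synthetic renderer); it is not competitive with published detectors
  on hard real-world data and is deliberately simple. Real detectors plug
  in through `PupilDetector`.
* Pupil foreshortening error is not corrected computationally; like the
  hardware design this mirrors, it must be minimised experimentally
  (chin rest, on-axis camera placement).
* One eye per image; two-eye scenes need an ROI over the target eye.
* `verify_calibration` assumes the held-out views contain full corner
  grids; partial detections are discarded upstream by the collector.
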