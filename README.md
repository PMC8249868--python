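# stereopupil

An open stereo pupillometry measurement pipeline: dark-pupil ellipse
detection with fit-confidence metrics, single- and stereo-camera
calibration with reprojection-error validation, triangulation of ellipse
endpoints into an **absolute pupil diameter in millimetres**, and a
two-step artifact filter for the recorded time series. A seeded synthetic
eye/rig simulator makes every stage testable offline, without cameras or
recorded data.

## Who this is for

Vision scientists and psychophysiologists measuring the pupil light
response or using pupil diameter as a cognitive biomarker need absolute
diameters with accuracy on the order of 10⁻² mm — effects of interest span
0.015–0.5 mm. Remote NIR dark-pupil imaging with a calibrated stereo pair
of industrial cameras delivers that accuracy, but commercial eye trackers
hide their detection algorithms and rarely state pupil-size accuracy at
all. This package implements the full measurement core of such a system as
a tested Python library plus a small CLI.

## The method

**Detection.** In a dark-pupil NIR image the pupil is a dark ellipse on the
brighter iris. The baseline detector thresholds the darkest pixels,
cleans the mask morphologically, selects a connected component by area and
axis-ratio gates, extracts a sub-pixel boundary contour, and fits an
ellipse (centre `c`, full axes `a ≥ b`, angle `θ`) by direct least squares.
Every fit is scored by three metrics in [0, 1]:

* *outline confidence* — boundary contrast `clip((μ_out − μ_in)/T_sat, 0, 1)`
  between mean intensities just outside and just inside the ellipse;
* *axis ratio* — `b/a`, the fit's foreshortening/distortion;
* *angular edge spread* — the fraction of angular sectors around the centre
  that contain boundary support points.

Detectors with no native confidence use the mean of the three.

**Calibration.** Intrinsics `K = [[f_x, 0, c_x], [0, f_y, c_y], [0, 0, 1]]`
and distortion coefficients `C = (k₁, k₂, p₁, p₂, k₃)` are estimated from
chessboard views by Zhang's planar-target method (closed-form
initialisation from view homographies, then full bundle refinement).
Quality is reported as per-point Euclidean RMSE and MAE reprojection error,
plus a held-out verification MAE with frozen parameters. Stereo
calibration estimates the relative pose `(R, T)` of the secondary camera
and builds the projection matrices `M₁ = K₁[I|0]`, `M₂ = K₂[R|T]`; absolute
quality is validated by triangulating the chessboard corners and comparing
every adjacent-corner distance with the known square size.

**Measurement.** For each synchronized frame pair (matched by hardware
frame count, never by timestamp), the endpoints of the pupil ellipse's
major axis are extracted in both images, undistorted, and triangulated by
homogeneous linear least squares (DLT); homogeneous results convert to
Cartesian coordinates with `ω = W_H` when `W_H ≠ 0` and `ω = 1` otherwise.
The absolute diameter is the Euclidean distance of the two world points.

**Pre-processing.** Recorded series are cleaned in two steps:
(1) remove every sample whose outline confidence is strictly below 1 —
this catches eye blinks; (2) remove strong outliers of the inter-camera
axis-ratio difference (beyond `k = 3` robust SDs, `1.4826·MAD`) — this
catches stereo matching-point errors. Filters only flag records; raw
values are always recoverable.

## Worked example

Simulate the reference rig (two 2048×1536 px cameras, f = 14493 px,
75 mm baseline, 8° vergence, 700 mm working distance) viewing a 5 mm
reference disk for 3000 frames with realistic artifact rates, then measure
and filter:

```python
import numpy as np
from stereopupil import SimConfig, PupilSeries, simulate_reference_sequence
from stereopupil.preprocess import two_step_preprocess, invalid_data_rate

cfg = SimConfig(seed=5)                    # reference rig, 5 mm test object
seq = simulate_reference_sequence(cfg, n_frames=3000)
diameters = seq.measured_diameters()       # triangulated, mm
print(f"raw MAE:          {np.nanmean(np.abs(diameters - 5.0)):.4f} mm")

series = PupilSeries.from_simulated(seq)
filtered = two_step_preprocess(series)
kept = filtered.surviving["diameter_mm"]
print(f"filtered MAE:     {np.abs(kept - 5.0).mean():.4f} mm")
print(f"invalid data rate: {invalid_data_rate(series, filtered):.2f} %")
```

Output:

```
raw MAE:          0.0085 mm
filtered MAE:     0.0020 mm
invalid data rate: 2.87 %
```

The raw mean absolute error (0.0085 mm) is dominated by the injected blink
and matching-point artifacts; after the two-step filter removes them
(2.87% of samples), the remaining error (0.0020 mm) is the endpoint-noise
floor of the rig geometry — about 0.05 px at ≈0.048 mm/px.

The same pipeline is available from the shell:

```sh
stereopupil trigger --count 100 --interval-ms 10     # -> <Tx100x5000>
stereopupil simulate --n-frames 3000 --seed 5 --out run/
stereopupil preprocess --input run/measurements.csv --out run/filtered.csv
```

## Scope

Live camera acquisition (vendor SDKs), GUI, microcontroller firmware and
re-implementations of published third-party pupil detectors are out of
scope; third-party detectors plug in through the
`stereopupil.detect.PupilDetector` interface. See `docs/methods.md` for
model details, parameter defaults, numerical choices and known limitations.
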