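# Methods

## Model

The estimator treats the walking body as an inverted pendulum whose mass is
concentrated at the centre of mass (CoM), assumed to lie within the pelvis.
While only the feet contact the ground, Newton's second law gives the total
ground reaction force as

    GRF = m · (a_CoM − g) = m · f_CoM

where `f_CoM` is the CoM *specific force* — exactly what an accelerometer
rigidly attached at the pelvis measures (it reads +g upward at rest).  The
whole pipeline is therefore: rotate the accelerometer signal into the right
frame, multiply by mass, and clean up.  What makes this non-trivial is the
frame: the estimate must be expressed in a body-centric, per-step
"initial-contact" frame (X forward along the step heading, Z vertical) so
that the output is independent of any fixed global frame, uses no
magnetometer, and is immune to heading drift.

Assumptions inherited from the model: no external contacts other than the
feet, CoM acceleration well approximated by pelvis acceleration, and a total
(not per-foot) force.  Left/right decomposition is out of scope.

## Pipeline stages

1. **Calibration** (`calibration`).  The protocol provides a quiet stance
   and three forward trunk bows.  Stance fixes pelvis +Z (normalised mean
   specific force) and the initial gyroscope bias (window mean; a stillness
   screen of 0.05 rad/s per-axis standard deviation rejects windows with
   motion).  The bow fixes the mediolateral +Y axis as the first principal
   direction of the bow-window angular rates, signed so the first bow pitches
   forward (+Y is left, X = Y × Z is anterior).  A bow axis within 15° of
   vertical is rejected as indistinguishable from a turn.  The construction
   is mounting-invariant: re-mounting the sensor by any rotation changes the
   recovered sensor-to-pelvis matrix by exactly that rotation (verified to
   <1° over random mountings).

2. **Initial-contact detection** (`gait_events`).  Pelvis acceleration is
   low-pass filtered (2 Hz, order 2, zero phase), its magnitude mean-detrended,
   and strict local maxima with topographic prominence ≥ 0.2 m/s² are taken
   as contacts.  Detected peaks reflect the loading response, which lags the
   true foot strike; a uniform offset (default 0.08 s, signed and
   configurable) is subtracted.  A 0.25 s minimum inter-contact interval
   resolves double peaks in favour of the higher one.

3. **Orientation tracking** (`orientation_eekf`).  An error-state extended
   Kalman filter integrates the bias-corrected gyroscope
   (right-multiplication by the axis-angle exponential) and tracks two error
   states: a right-multiplied body-frame orientation error and the gyro bias
   error.  The accelerometer corrects inclination only — the innovation is
   the discrepancy between the measured specific-force direction and the
   predicted body-frame vertical.  Rotation about the vertical lies in the
   measurement's null space, so heading is gyro-integrated only and its
   covariance grows without bound (by design; the per-step frame absorbs
   it).  After each update the orientation is corrected by the small-angle
   factor (I − θ̃), re-orthonormalised (SVD polar projection), and the error
   reset.  Updates are skipped when | ‖a‖ − g | exceeds a 2 m/s² gate:
   gravity then no longer dominates the reading.

4. **Per-step frames** (`step_frames`).  Within each step, accelerations
   expressed in the previous step's frame are gravity-subtracted, integrated
   from zero, and high-pass filtered (2 Hz, order 2, zero phase) to the
   high-frequency CoM velocity; the high-pass annihilates the arbitrary
   integration constant.  The step heading is the horizontal direction of
   that velocity at its peak; the frame update is the pure yaw taking the
   heading to +X with Z pinned to the vertical.

5. **Force estimate** (`grf_pipeline`).  Newton's law, then impact-peak
   removal around each contact (see below), then axis-specific zero-phase
   Butterworth filtering: X band-passed 0.1–5 Hz, Y band-passed 0.1–3 Hz,
   Z low-passed 10 Hz, all order 2.  The 0.1 Hz high edge is what forces
   quiet-standing shear to 0 %BW; the Z low-pass keeps the full
   weight-support DC, so quiet standing reads 100 %BW vertical.
   %BW = 100 · F / (m·g) with g = 9.81 m/s².

6. **Reference chain** (`reference_pipeline`).  Summed per-foot forces; 30 N
   force-magnitude threshold crossings (0.1 s refractory) as contacts; CoM as
   the four-marker centroid; acceleration by double differentiation plus
   10 Hz low-pass with the gravitational reaction added on Z; velocity by
   re-removing gravity, integrating, and 2 Hz high-passing — deliberately
   mirroring the IMU path so both body-centric frames are built alike.

7. **Agreement metrics** (`metrics`).  Per-axis RMS of differences in %BW
   and RMS of the magnitude difference; Pearson correlation per axis over
   the complete trial (standing, initiation, turns and termination
   included — no gait-cycle normalisation); RMS error normalised by the
   reference range; Bland–Altman mean difference with 25th/75th percentiles
   (linear interpolation, pinned by a golden test) for the shear-magnitude
   and vertical comparisons; and the per-step angle between the two systems'
   heading vectors, interior steps only.

## Heading bootstrap and robustness

The first step has no predecessor frame, so the chain is run once over the
first three steps from a tilt-aligned, arbitrary-heading initial orientation;
the yaw correction that maps the most vigorous of those steps' headings to +X
is then applied to the initial orientation.  Anchoring on the strongest step
rather than literally the first matters in practice: the first detected step
usually straddles gait initiation, where the high-frequency velocity is still
ramping up and its direction is unreliable.

Two validity screens decide whether a step's heading is trusted at all
(untrusted steps reuse the previous heading — the frame update degenerates to
the identity, which also lets the pipeline survive standing spans inside a
trial):

* an absolute floor of 0.05 m/s peak horizontal velocity — far below the
  0.1–0.2 m/s within-step fluctuation of actual walking but above integrated
  sensor noise, so noisy quiet standing never manufactures headings;
* a trial-relative floor of 50 % of the strongest step's peak velocity, plus
  unconditional exclusion of the first and last steps of a trial: initiation
  and termination fragments carry genuine backward high-frequency velocity
  (acceleration/deceleration transients) whose "heading" would rotate the
  frame by up to 180°.

The velocity-peak search also skips the zero-phase filter's warm-up samples
(3 × order at each end of the step window), where the filtered values are
transients, not signal.

## Numerical choices

* **Zero-phase filtering** uses reflective (even) signal extension before
  the forward-backward pass.  The pad is sized to the filter's
  impulse-response length (slowest pole decayed to 1e-12), capped at the
  series length − 1; this makes the operation time-reversal symmetric to
  ~1e-13 and preserves DC exactly.  The per-step velocity high-pass is the
  one exception: on a sub-second window a long mirrored extension would
  swamp the window with reflected integration drift, so it uses a short
  3 × order pad and the warm-up exclusion above.
* **Peak prominence** follows the classical topographic definition; for
  equal-height summits the leftmost acts as the parent (keeps full
  prominence) while the others are measured against the connecting saddle.
  The implementation is pinned against an exhaustive O(n²) oracle.
* **Impact-peak removal**: within ±0.10 s of each contact, per axis, the
  sample deviating most from the window's order-3 Savitzky–Golay fit (the
  impact extremum) is excised by linear interpolation over its ±2-sample
  neighbourhood and the window re-smoothed with the same filter, blended
  over 3 samples at the window edges.  Outside the windows the signal is
  bit-identical.
* **Filter-state tuning**: gyro noise density 5e-4 rad/s/√Hz (consistent
  with an MTw-class gyro and with the synthetic sensing chain: 0.005 rad/s
  white at 100 Hz), bias random walk 1e-4 rad/s²/√Hz, accelerometer
  direction noise 0.5 m/s², gate 2 m/s², P₀ = diag(1e-2 rad² ×3,
  1e-4 (rad/s)² ×3).  All exposed in the run configuration.
* **Frame-update argmax ties** break to the first index; degenerate steps
  reuse the previous heading; mass·g (not a measured force plateau) is the
  %BW denominator.

## Synthetic gait generator

The simulator (`synthetic`) is a kinematic prescription, not a dynamics
simulation: a CoM trajectory is written in closed form and every measured
stream is derived from it, so the estimator's own model (GRF = m · f_CoM)
holds exactly and the generator is a legitimate oracle.

A trial follows the measurement protocol: 3 s quiet stance, three 2 s
forward bows (30°), 2 s stance, the walking task, 2 s stance.  Tasks: NW
(5 m straight), LW (3 m, 90° right, 2 m), WT (5 m, 180°, back), WT2
(out–back–out), SlW (±30° slalom), standing.  Defaults describe a healthy
adult: 74.3 kg, 1.2 m/s, 1.8 initial contacts per second.

Gait signature: vertical CoM oscillation (amplitude 18 mm) at the step
frequency, lateral oscillation (35 mm) at the stride frequency (half the
step rate), and a fore-aft fluctuation (12 mm fundamental plus a 2nd
harmonic at quarter amplitude).  True initial contacts sit at the lateral
zero crossings — the CoM starts moving toward the new stance side.  Two
phase choices encode gait physiology the estimator relies on: the
vertical-acceleration peak of each step trails the contact by 0.08 s (the
loading-response lag the detector's uniform offset corrects), and the
fore-aft velocity peak is sharp, its trough shallow, and the peak coincides
with the CoM's lowest point just after contact (pendular energy exchange;
the second harmonic provides the asymmetry).  Speed ramps follow a cosine
profile over 0.6 s at the walk edges; contacts are only emitted where the
speed factor exceeds one half.  Per-foot forces share the total through
sinusoidal double-support ramps (20 % of a step); the measured total is
defined as the per-foot sum, so the split is exact by construction and
swing-phase force is exactly zero.  Markers are four fixed pelvis-frame
offsets with zero centroid, so the marker centroid coincides with the CoM.
The sensing chain adds per-axis white noise (accelerometer 0.05 m/s²,
gyroscope 0.005 rad/s), a constant gyro bias of order 0.01 rad/s, and an
arbitrary sensor mounting rotation; every level scales to zero so estimator
errors are attributable to the algorithms alone.

What the generator does *not* emulate: impact transients (beyond spikes
injected explicitly in peak-removal tests), soft-tissue artefact, CoM
excursion during the bows (the pelvis rotates with the CoM held fixed,
keeping |a| = g through the calibration segment), asymmetric or impaired
gait, and any musculoskeletal realism.  Passing tests therefore show the
pipeline is correct under its own model with realistic magnitudes and
sensor noise — not that it reproduces results on recorded human data.

## Study conditions used by the validation suite

Tests and the acceptance script run at desk scale: single trials of ~18 s
at 100 Hz (5 m walks), 20-seed parameter-recovery sweeps of 30 s stance
sequences, and a 10⁵-cycle orthonormality run.  On noise-free normal
walking the end-to-end estimate stays within 3 %BW RMS of the simulator
truth on every axis (2.5 / 1.5 / 0.3 %BW measured for X/Y/Z), essentially
unchanged under default sensor noise; turning tasks are harder (4–20 %BW,
growing with the number of heading changes),
dominated by per-step frame timing around the turns — the same pattern the
underlying method shows on real data, where heading-change tasks have the
largest shear errors.  The reference chain recovers the simulator truth to
<1 %BW RMS on straight walking, qualifying it as the comparison oracle for
the metrics layer.

## Known limitations

* Heading is defined by the high-frequency CoM velocity within a step; at
  gait initiation/termination and during sharp turns this direction is
  genuinely ambiguous, and frame-timing differences dominate the shear
  error there.
* The inclination update assumes gravity dominance; sustained high-dynamics
  motion (running) starves the filter of tilt corrections.
* The bowing calibration needs a clean forward bow; bows contaminated by
  axial rotation shift the mediolateral axis estimate.
* Total GRF only; single-support force equals total force but double-support
  decomposition is not attempted.
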