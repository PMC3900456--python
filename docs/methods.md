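# Methods

This note documents the models, algorithms, parameter choices, and known
limitations of the package. It complements the README's overview with the
detail a user needs to judge what the outputs mean.

## Data model and conventions

Loads live in a coordinate system fixed to a right-sided tibial component:
Fx lateral +, Fy anterior +, Fz axial (the compressive contact load acts
distally, so the physiological axial force is −Fz, positive), Mx/My/Mz
positive for tibial flexion/abduction/outer-rotation torques. Forces are
stored in %BW and moments in %BW·m throughout the analysis; conversion to
N/N·m happens only when the standardized levels are built. Raw Fz is kept
with its sign and −Fz is exposed through accessors, so no sign information
is destroyed.

Left-knee recordings are pooled with right-knee ones by mirroring about the
sagittal plane (x → −x): Fx, and the pseudo-vector components My and Mz,
change sign; Fy, Fz, Mx do not. The mirror is an involution and preserves
both resultants exactly.

The optional tibia-frame transform rotates force and moment vectors about
the x-axis by −(posterior slope); it is an orientation change only (the
moment reference point is not moved), so F_res and M_res are invariant.
Only the rotation direction is a convention; it is stated here and in the
docstring so users with the opposite convention can negate the angle.

Unit conversion: a pattern in %BW becomes newtons for body mass X via
9.81·X/100 (7.36 at 75 kg, 9.81 at 100 kg), applied to the six load
channels and resultants. The flexion channel is an angle in degrees and is
deliberately never rescaled by load factors.

## Segmentation

* **Walking/jogging**: cycle boundaries are upward crossings of F_res
  through a contact threshold of 20 %BW, debounced on both sides (the
  signal must sit below the threshold for 5 consecutive samples before the
  crossing and at/above it for 5 after). 20 %BW sits far below stance loads
  (≥ 150 %BW) and comfortably above swing-phase noise; the two-sided
  debounce rejects single-sample noise spikes.
* **Stairs**: swing phases are intervals where the smoothed F_res falls
  below 30 % of the median stance peak; the boundary is the force minimum
  inside each *interior* interval, so leading/trailing partial cycles are
  discarded.
* **Non-cyclic exercises** (knee bend, chair rise/sit, one-legged stance):
  the baseline is the median of the smoothed F_res over the first and last
  10 % of the record; the exercise interval is where the *raw* F_res
  exceeds baseline + 25 % of the excursion. Raw-signal thresholding keeps a
  sharp onset located to the sample (a smoothed signal would blur a step
  edge by half the smoothing window); the mid-range threshold makes the
  raw comparison noise-safe. The interval is padded by 5 % of its length
  per side (clipped to the record), since such exercises are reported with
  short lead-in/lead-out intervals.
* Smoothing, where used, is a centered moving average with a window of 5 %
  of the activity's expected cycle time — deterministic and parameter-free
  beyond that single fraction.

Cycles are resampled onto a uniform 0–100 % grid of **201 points** (0.5 %
steps) by linear interpolation; original durations are retained and their
arithmetic mean is reported as the activity's cycle time T_c.

## Time-warping average

The registration problem: find monotone, endpoint-anchored time
deformations of n cycles minimizing the summed squared difference of their
F_res curves over the cycle. The implementation is iterated template
registration:

1. the template starts as the pointwise mean;
2. each cycle is aligned to the template by dynamic programming over
   integer grid correspondences j_0 = 0, j_{N−1} = N−1,
   j_{i+1} − j_i ∈ {0, 1, 2}, with the additional symmetric slope
   constraint that a 0-step (template stands still) or a 2-step (template
   skips) may not immediately repeat — the local warp slope stays within
   [1/2, 2];
3. warped curves are obtained by resampling each cycle along its path
   (values at duplicated knots are averaged — at most two adjacent samples
   under the slope constraint); the template is recomputed as their mean;
4. iterate until the relative decrease of the objective (summed squared
   deviation of warped curves from the template) falls below 1e−6 or 50
   iterations; the best state is tracked, so the reported objective is
   non-increasing and never exceeds that of the unwarped mean.

Two deliberate design choices:

* **Amplitude-normalized alignment.** The DP runs on curves divided by
  their own peak value; the resulting paths are applied to the raw curves.
  Without this, the least-squares optimum for a cycle that is simply a
  scaled-up copy of the template is a degenerate "pinch" path that piles
  the peak samples onto the template maximum and flattens the amplitude —
  precisely the artifact a time-only deformation must not introduce.
  With normalization the DP compares shapes; warping preserves each
  cycle's extremum amplitudes to within interpolation error (≈ 1 % of the
  channel range, enforced by tests).
* **Slope constraint.** Limiting the step family (no repeated 0- or
  2-steps) bounds amplitude distortion from duplicate-averaging and
  preserves the characteristic behaviour that a relative maximum present
  in only half of the cycles, at varying times, survives averaging at
  about half its height. The DP is exact for this step family; tests
  verify it against exhaustive path enumeration on small instances.

Tie-breaks in the DP prefer the diagonal step, then the template skip,
then standing still, making results reproducible. The paths fitted on
F_res are applied to all channels of the same cycle, so components keep
their synchronization; the averaged pattern stores both the mean of the
warped F_res curves (the optimized quantity, reported as F_res) and the
resultant of the mean components (norm of a mean ≤ mean of norms; the two
are stored separately and never conflated).

## Standardized levels

Averaging is hierarchical: cycles are warp-averaged within each subject,
then the subject patterns are warp-averaged across subjects (each subject
pattern enters as one pseudo-cycle; T_c averages accordingly). The peak
registry is taken from global F_res maxima: P1 on the population pattern,
P2 the largest subject-pattern peak, P3 the largest single-cycle peak over
all trials (both measurement sessions may be pooled to broaden this
search). Factors: F_H = P2/P1, F_P = P3/P1, C_aver = 1/((100/75)·F_H),
C_peak = F_P/F_H. The body-weight ratio is computed as 100/75 exactly, not
the display-rounded 1.33.

AVER75 = population pattern × 7.36; HIGH100 = AVER75 × (100/75) × F_H;
PEAK100 = HIGH100 × C_peak by default, which keeps the average shape and
scales its peak to P3. An alternative (`peak_shape="trial"`) rescales the
single highest trial's own components instead, retaining that trial's load
directions; the default is the conversion-factor definition because it is
the one the factor table operationalizes. All factors are applied
identically to every load component, so the three levels share their load
directions.

## EXTREME100

Reference peaks per component are relative extrema of the lightly smoothed
average pattern with prominence ≥ 5 %BW (forces) / 0.5 %BW·m (moments),
ranked by absolute value, at most 3 kept, numbered in time order. Each
trial is searched within ±15 % cycle of the reference time for a relative
extremum of the same kind: a matching-sign extremum yields the trial's
value; an opposite-sign extremum excludes the trial as a sign conflict; no
extremum (a shoulder without a derivative sign change counts as none)
excludes it as absent. The most extreme matched value over all trials is
reported at 100 kg (×9.81), with provenance and the three exclusion counts,
which always sum to the number of trials. The ±15 % window is wide enough
for observed peak-timing variability yet narrow enough to keep peak
identity; both thresholds exist only to suppress noise extrema and are
exposed as parameters.

## Wear-test comparison

The reference waveform (axial force, a/p force, rotation torque, flexion)
is always a user-supplied file — the ISO 14243 tables are licensed content.
Channels map to −Fz, Fy, Mz of the measured HIGH100 set. Each reference
extremum is paired with the nearest measured extremum of the same kind
within ±20 % cycle; the reported difference is
100·(measured − reference)/|reference|, a signed convention chosen because
it is unambiguous and antisymmetric up to the denominator change (a
"percent smaller" phrasing bounded at 100 % cannot express the observed
several-fold discrepancies). Reference peaks without a measured
counterpart are flagged as lacking.

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes:

* **Templates** are shape-preserving (PCHIP) curves through planted control
  points per activity — two-peaked walking stance (peaks ≈ 230/260 %BW at
  15/48 % cycle), single-peaked jogging (≈ 420 %BW), min-to-min stair
  cycles (two peaks ≈ 300–315 %BW), single-plateau non-cyclic exercises
  (≈ 265–285 %BW over a ≈ 45–50 %BW two-legged-stance baseline). −Fz is
  derived from the planted F_res and the in-plane forces so the component
  resultant reproduces F_res exactly and −Fz ≈ F_res.
* **Subject scales** are log-normal with σ = 0.18, chosen so that the
  max/mean ratio over 8 subjects is typically ≈ 1.25–1.4, matching the
  inter-individual spread implied by conversion factors C_aver ≈ 0.53–0.60.
  `subject_scales_with_ratio` plants an exact max/mean ratio for recovery
  tests.
* **Timing variability**: per-cycle random warps (normalized integrals of
  exp of a low-order random sine series; strength 0.15 bounds the slope
  deviation) plus ±5 % uniform duration jitter around the activity's cycle
  time from the study's activity table (walking 1.07 s, etc.).
* **Noise**: additive Gaussian on each component (3 %BW forces,
  0.3 %BW·m moments — within the implant's ≈ 2 % measurement accuracy
  against stance peaks of 230–420 %BW); F_res is always recomputed from
  the noisy components, never noised independently.
* **Sign variability**: per-subject sign flips of transverse components
  (Fx, My, Mz) with configurable probability, emulating the observed
  inter-individual sign differences; F_res is invariant to them.
* Everything derives from one seed; identical seeds give byte-identical
  trial files.

What the generator does **not** emulate: within-cycle amplitude shape
changes between subjects (all subjects share one template up to scale,
warp, and sign), correlated noise, soft-tissue or implant-design
differences, slow postoperative trends, and marker-based kinematics (the
flexion channel is a template curve, not a simulated measurement). Passing
recovery tests therefore shows the pipeline is correct under the stated
statistical model, not that real telemetry meets that model.

## Problem sizes and numerics

Recovery tests use 8 subjects × 20 cycles (the study's walking scale) on
the 201-point grid; oracle-equivalence tests use 9–15-point instances where
exhaustive path enumeration is feasible. Degenerate inputs are handled
explicitly: a single cycle returns an identity path with zero objective;
flat channels yield no reference peaks; specs with no matching trial are
omitted with a warning rather than fabricated. Convergence tolerance 1e−6
(relative objective change), maximum 50 iterations; in practice
registration converges in well under 10.

## Known limitations

* The DP grid correspondence is integer-valued on the 0.5 % grid, so
  recovered warps are quantized to one grid step and unidentifiable over
  flat signal regions.
* With very few cycles, P3 (and hence F_P, C_peak) is an extreme-value
  statistic and noisy by nature.
* Cycle boundaries for walking are threshold crossings, so averaged
  patterns carry a small constant phase offset (≈ 1 % cycle for the
  synthetic template) relative to a boundary defined at force onset.
* The standardized levels assume load directions scale with magnitude; the
  EXTREME100 table exists precisely because individual components violate
  that assumption, and its values stem from different subjects — they may
  never co-occur in one person.
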