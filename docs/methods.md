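# Methods

This note documents the models, parameter choices and numerical decisions
behind `mobilikit`, and what the synthetic-data validation does and does
not establish about real recordings.

## Problem setting

Two clinical tests are analysed from head-worn sensors. In the five-time
sit-to-stand (STS) the participant rises from and returns to a chair five
times as quickly as possible; in the timed up and go (TUG) they rise,
walk 3 m, turn, walk back and sit down. Two channels observe the same
movement: a fused head-position stream at a jittered ~30 Hz (the device
under validation) and a gravity-corrected accelerometer at 128 Hz (the
reference). The pipeline derives vertical displacement/velocity/
acceleration from both, quantifies their agreement, and extracts the
timing and kinematic features clinicians use.

Orientation estimation and gravity alignment are out of scope: the
accelerometer input is assumed already gravity-corrected, and only the
vertical (VT) axis is analysed quantitatively. The anterior-posterior
axis is simulated (for the 3 m walk) but not drift-corrected — there is
no analogue of the chair-contact constraint during walking.

## Processing chain

1. Resample both channels onto a uniform 30 Hz grid anchored at the first
   timestamp (linear interpolation — robust to clock jitter, no
   ringing).
2. Zero-phase 4th-order Butterworth low-pass at 5 Hz. Zero-phase
   (forward–backward) filtering is the default throughout because
   signals are compared sample-by-sample; any phase lag would bias NRMSE
   and the lag estimate. A single-pass mode exists for applications that
   need causality. Edge transients are suppressed by reflect padding of
   about three cutoff time constants.
3. Double-integrate the accelerometer channel (trapezoid rule, zero
   initial conditions — trials start seated and stationary; residual
   offsets are absorbed by drift correction).
4. Correct the integration drift (below).
5. Differentiate to velocity and acceleration (central differences),
   low-passing the derivatives at 5 Hz; the displacement itself is not
   re-filtered so that ZDU anchors remain exact zeros.
6. Align the two displacement signals by normalized cross-correlation
   and apply the same integer-sample lag to all three quantities.
7. Score agreement per quantity (NRMSE, zero-lag Pearson correlation)
   and extract features.

## Drift correction

A constant accelerometer bias b integrates to a displacement error
b·t²/2; a bias ramp b₁ adds b₁·t³/6; white noise adds a random walk with
sd growing as t^{3/2}. Two corrections are provided and selectable
(`drift = none | hpf | zdu | hpf+zdu`):

* **High-pass filter** — zero-phase 4th-order Butterworth at 0.1 Hz on
  the integrated displacement. On records shorter than ~10 s the filter
  cannot settle (a warning is emitted); on the 10–14 s trials here it
  removes only part of the drift, which is why it is not the default.
* **Zero-displacement update (ZDU)** — the default. Chair contacts are
  instants of known zero displacement; a continuous piecewise-linear
  curve through the measured displacement at those instants is
  subtracted, with edge-segment extrapolation outside the first/last
  contact. Linear segments remove a constant-bias error exactly up to
  the chord deviation b·Δ²/8 per inter-contact gap Δ; a continuous
  correction (rather than a stepwise one) avoids velocity spikes on
  differentiation. Contacts are snapped to the sample grid, so corrected
  displacement is *exactly* zero at the anchor samples.

For STS the ZDU re-anchors every ~2.7 s (six contacts for five
repetitions, counting the seated start). For TUG only the start and end
of the recording are seated, so the correction degenerates to a
single-span linear detrend and a quadratic residual of order
b·T²/8 remains mid-trial. With the default simulated bias this residual
exceeds the 0.3 m movement itself, so TUG displacement agreement is
reported as poor — the expected behaviour of single-span correction, not
a defect. The per-cycle/single-span choice is automatic by task and
overridable (`zdu_single_span`).

### Contact detection

The detector takes the candidate regions where displacement lies within
25 % of its range above the global minimum (the seated band), merges
regions closer than `min_separation` (default 1.0 s), and places the
contact at the first instant inside each region where the vertical speed
has fallen below 5 % of its peak — the moment the descent actually ends
on the chair. A plain local-minimum rule was rejected: on a flat seated
hold corrupted by noise the minimum is uniformly distributed over the
hold, giving contact errors up to the hold duration, whereas the
velocity rule stays within ~0.1 s of the true contact.

On the inertial path the raw integrated displacement drifts by metres,
defeating any amplitude-based detector, and the 0.1 Hz high-pass cannot
settle on these record lengths. Detection therefore runs on a
cubic-polynomial-detrended copy (a cubic is exactly the integral shape
of the b₀ + b₁t bias model); the ZDU itself is applied to the
uncorrected signal. For the same reason the cross-device lag is
estimated on cubic-detrended copies of the displacement signals —
otherwise the residual drift, not the movement, dominates the
correlation; agreement statistics are computed on the actual signals.

## Phase segmentation and features

A rise candidate is a stretch where vertical velocity exceeds 10 % of
its peak magnitude for at least 0.1 s; onset and offset are refined
backward/forward to the nearest velocity zero crossing, where movement
truly starts and stops (exact on minimum-jerk profiles, whose velocity
vanishes only at transition boundaries). Descents are symmetric on
negative velocity. A candidate is kept only if the displacement change
across it reaches 50 % of the trial's displacement range; this guard is
what lets TUG trials pass through segmentation with exactly one
rise/descent despite vertical gait bounce crossing the velocity
threshold during walking.

Features follow the clinical definitions: STS total time = first rise
onset to last descent offset; stand phase = rise movement duration; sit
phase = descent movement duration (the movement, not the seated dwell —
consistent with sub-second stand times and ~1 s sit times); maximum
velocity is the peak *upward* velocity and maximum acceleration the peak
magnitude, both within the active window. "Completion of the last
descent" is interpreted as movement end (velocity back below threshold)
rather than chair contact; the two differ by only a few samples on
smooth profiles.

## Agreement statistics

* NRMSE = 100·RMSE/(max−min) of the **reference** (inertial-role)
  signal; using one denominator per pair keeps values comparable across
  device pairs. The denominator choice is exposed by passing the other
  signal as `reference`.
* Xcor = Pearson correlation of the aligned samples at zero lag.
* Lag estimation scans integer-sample shifts within ±2 s, normalizing
  each shift's correlation by the overlapping segments' norms
  (amplitude-invariant); ties prefer the smallest |lag|.
* Confidence intervals use the Student-t multiplier, not 1.96 — per
  condition there are only tens of trials.
* Bland-Altman limits of agreement: mean difference ± 1.96 × sample sd
  (n−1); the per-pair (mean, difference) points are returned for
  plotting.
* The group comparison uses the pooled-variance two-sample t-test (the
  classical "Student" form); Welch's correction is available by flag.

## The synthetic-data generator

Chair transfers are minimum-jerk quintics s(τ) = H(10τ³ − 15τ⁴ + 6τ⁵) —
the standard smooth model of point-to-point human movement, with peak
velocity 1.875·H/T and peak acceleration (10/√3)·H/T². Defaults
reproduce the test protocols: five repetitions, vertical head excursion
H = 0.30 m, rise 0.6 s, descent 1.0 s, 0.5 s holds (≈13.5 s per STS
trial); TUG adds a 3 m walk at 1 m/s modelled as a minimum-jerk
anterior-posterior reach, a 1 s turn plateau and a vertical bounce of
0.015 m at twice the 2 Hz gait-cycle rate (one oscillation per step),
ramped on/off smoothly at bout boundaries. Ground truth is analytic;
displacement returns exactly to zero at every chair contact and the
anterior-posterior excursion peaks at exactly 3 m.

Sensor models: the inertial channel is truth acceleration at 128 Hz plus
white Gaussian noise (sd 0.1 m/s²) and a bias b₀ + b₁t
(0.05 m/s² + 0.005 m/s³) — the minimal model producing the
quadratic/cubic drift the corrections exist to remove; the position
channel is truth displacement at 30 Hz with Gaussian clock jitter (sd
5 ms, clipped to 40 % of the period so the clock stays monotone) and
5 mm white noise. No public noise specifications exist for either device
class; these magnitudes were fixed once as plausible for consumer-grade
hardware and are configuration, not claims about any specific sensor.
All randomness derives from a single seed; identical configurations give
bit-identical trials.

What the generator does **not** emulate: inter-repetition variability in
amplitude or tempo, asymmetric or paused transfers, trunk-versus-head
coupling differences between sensor sites, turning dynamics or the
medio-lateral axis, and real accelerometer error structure
(temperature-dependent bias walks, scale-factor error, misalignment).
Passing tests therefore establish that the *pipeline* is correct and
self-consistent under its stated noise model — not that any particular
hardware meets a given agreement level.

## Numerical notes

* Trapezoid double integration of a 128 Hz-sampled minimum-jerk profile
  carries a ~1 mm/cycle systematic error because the jerk steps at
  segment boundaries fall between grid points (h²·Δjerk/12 velocity
  residual per transition); over a five-cycle trial this is ~5 mm,
  negligible against the drift being corrected but visible in
  noise-free tests.
* The integrate-then-differentiate round trip reproduces a signal to
  x + h²x″/4; sub-1e-6 recovery at 128 Hz therefore holds only for very
  slowly varying inputs.
* The digital (bilinear) Butterworth magnitude deviates from the analog
  form (1+(f/fc)^{2n})^{−1/2} by tan-frequency warping — ~6 % at 2fc
  when fc/fs = 5/128. Filter-fidelity tests run at sampling rates where
  warping is below the tolerance; at fc the −3 dB point is exact at any
  rate thanks to prewarping.
* Resampling grids are anchored at the first timestamp and never
  extrapolate; trial durations are quantized to the sample period.
* Degenerate inputs fail loudly and specifically: constant signals raise
  no-contact/no-movement errors, constant correlation inputs are
  rejected, a zero reference range makes NRMSE undefined, and the
  zero-variance t-test returns (0, 1) for equal means by contract.

## Problem sizes

The test suite and acceptance script run entirely on simulated data:
20–100 trials per statistic (each ~13.5 s at 128 Hz), 200 Monte-Carlo
runs for noisy lag recovery, 1000 replicates for CI coverage. These
sizes give stable medians/means for the qualitative orderings and
sub-0.01 precision on the reported statistics while keeping the whole
suite in the seconds range.
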