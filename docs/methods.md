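# Methods

This note documents the models, signal-processing choices and synthetic
data behind `gaitkine`, and what the package's tests do and do not
demonstrate.

## Input model

The pipeline consumes the *fused* output of a GPS-aided inertial
navigation sensor (INS/GPS) worn on the torso: NED velocity, acceleration,
angular velocity and an orientation quaternion at 400 Hz. The sensor's
internal error-state Kalman filter is treated as a black box — we rely
only on its published output contract (velocity accuracy ±0.05 m/s,
pitch/roll ≈0.1° RMS, heading ≈0.3° RMS). Optional instrumented-insole
logs (per-foot total vertical force at 50 or 100 Hz) provide ground truth
for contact and GRF; they are linearly interpolated onto the 400 Hz grid.
Missing samples are rejected, never imputed; gaps should be represented as
separate streams.

## Anatomical frame

For level walking and running, the anatomical frame reduces to horizontal
speed and direction of travel:

    V(t)   = sqrt(V_N² + V_E²)
    Psi(t) = atan2(V_E, V_N)

`atan2` (not plain `atan`) is required for southbound headings. Below a
stall speed of 0.3 m/s the heading of horizontal velocity is
ill-conditioned, so the last valid ground track is held — this threshold
and the hold rule are our choices. Pitch and yaw come from the quaternion
via the aerospace Z-Y-X convention. Vertical quantities are sign-flipped
from NED "down" to up-positive.

## Drift removal

Integrated vertical velocity drifts at low frequency (accelerometer bias,
inclines). Before segmentation and displacement integration we high-pass
filter with a minimum-order Kaiser-window FIR designed from the triple
(passband edge 0.005 of Nyquist = 1 Hz at 400 Hz, stopband attenuation
30 dB, steepness 0.7). The steepness places the transition band in the
(1 − 0.7) fraction of the band *below* the passband edge, i.e. stopband
edge 0.7 Hz — at the default spec the kernel is 2049 taps (~5.1 s).

Two deliberate numerical choices:

* **Single-pass, linear phase.** The symmetric odd-length kernel is
  applied once with exact group-delay compensation (centred convolution
  over odd-reflection padding). This gives exactly zero phase — crossing
  times of in-band components do not move — while keeping the designed
  passband ripple (±3.2%). Forward–backward filtering would square the
  ripple to ±6.5% in exchange for nothing we need.
* **Exact DC null.** The tap sum is subtracted out so the DC gain is
  identically zero rather than merely ≤ −30 dB.

The filter's edge transient contaminates half a kernel length (~2.6 s) at
each end of a window; steps overlapping that region are flagged irregular
and excluded from scoring. Trials must exceed 3 kernel lengths (~16 s).

## Step segmentation

A step starts when the filtered vertical velocity crosses zero going
negative — the CoM apex. Crossing detection uses a Schmitt trigger: a
crossing is recognized only after the signal has left a ±0.02 m/s dead
band on the other side, so noise wiggles inside the band can neither
create nor destroy events. Within a hysteresis transition the steepest raw
sign change is taken and its time refined by linear interpolation between
the bracketing samples (at 400 Hz, 2.5 ms/sample, sub-sample timing is
what makes the millisecond-level claims possible). Same-sign crossings
closer than a 150 ms refractory interval are merged, keeping the steepest.
The dead band, refractory interval and the irregularity rules below are
our values; only their existence, not their magnitudes, is dictated by the
method.

Segments are flagged irregular when: duration is outside [0.2, 1.5] s;
vertical-velocity peak-to-peak inside the step is below 0.1 m/s; duration
departs from the trailing 5-step median by more than 40%; or the segment
overlaps the filter's edge-transient region. Flagged segments never enter
metric computation.

## Per-step metrics

All integrals are trapezoidal with boundary values interpolated at the
sub-sample segment edges. Definitional identities hold exactly: cadence =
60/duration, mean speed = step length/duration. Vertical displacement is
the cumulative trapezoidal integral of the *filtered* vertical velocity,
referenced to the mean over the whole window (an integer number of steps),
so the CoM is highest at step boundaries and lowest mid-step; the per-step
closure residual (displacement change apex-to-apex, zero for ideal
level-ground gait) is reported as an error estimate. Forward lean is the
mean pitch over the step (the within-step statistic is not prescribed by
the method; the mean is our choice), body rotation the peak-to-peak of
unwrapped yaw minus ground track (relative to Psi, not to a fixed mean
heading — also our choice). Contact time is the stance duration of the
foot whose stance midpoint falls inside the step; with walking double
support one foot is grounded longer than a step, so the duty factor
(100·contact/step duration, following the definition used for running)
exceeds 100% in walking — we report it as computed rather than capping
it. Flight time/distance integrate over samples where neither foot is
grounded. Mechanical energy (½m(V² + v_z²) + mgh, g = 9.81) needs the
subject mass from configuration.

## Shift robustness

Because apex-based segmentation starts the cycle away from initial
contact, we quantify how metrics react to the choice of start: all
boundaries are translated by ±5…±30% of the mean step duration (a grid
translation, not per-step perturbations), metrics recomputed, and
per-step differences summarized (mean, SD, mean/max absolute and
relative). Relative differences are normalized by the per-step baseline;
the trial-level number quoted is the mean absolute relative difference.
Both means and maxima are exposed since either reading of "errors below
x%" is defensible.

## Indirect GCT/GRF estimation

The estimator maps the six inertial channels (3 acceleration, 3 angular
velocity) to per-foot contact probability (sigmoid head, masked binary
cross-entropy) or vertical GRF (ReLU head, masked MSE — the ReLU also
guarantees non-negative forces). Trials are windowed into 1201-sample
sequences with 50% overlap; inputs are scaled per channel by the 99.5th
percentile of |x| (a robust "roughly [−1, 1]" — impact spikes would
otherwise shrink the bulk of the signal); the loss ignores the first 601
samples of each window, and stitching takes only second halves, so every
scored sample is predicted with at least 1.5 s of context and covered
exactly once.

The network is implemented directly in numpy: stacked GRU and/or LSTM
cells with inter-layer inverted dropout, a dense head, full backprop
through time, Adam with gradient-norm clipping, and early stopping on a
contiguous validation tail (one boundary window dropped so train and
validation never share samples). The default architecture is a single
GRU(32) with dropout 0.15 — deliberately small; layer types are the only
architectural constraint of the method, widths and counts are free. Runs
are bit-reproducible under a fixed seed. Training is per-subject (here:
per-scenario); cross-subject transfer is out of scope.

Contact probability is binarized at 0.5 and 1-runs shorter than 40 ms are
discarded as spurious (both values ours). GCT is the run length over the
sample rate. nRMSE is RMSE normalized by the *range* of the reference —
with body-weight-scale force ranges this makes the few-percent GRF figures
meaningful; mean- or peak-normalization are not used. GRF can be trained
in newtons or body weights; the experiments use body weights (the
normalization cancels in nRMSE).

## Synthetic gait generator

The generator is the package's instrument for studying the pipeline; it
emulates the fused sensor output and the insole reference with full ground
truth (streams are derived from the truth, never the reverse).

Kinematics: within step k of duration d_k (cycle-to-cycle jitter 3% SD,
clipped at 3σ), phase φ = 2π(t − a_k)/d_k; vertical velocity
−(2πh_k/d_k)·sin φ (apex at φ = 0, per-step displacement peak-to-peak
exactly 2h_k); speed S(t) + B(t)·sin φ with S, B piecewise-linear across
steps plus a slow drift (0.05 m/s at 0.02 Hz); heading a slow sine around
a base bearing; pitch = lean + 1° oscillation; yaw swings ±3–4° about the
heading with alternating sign per step; roll sways at stride frequency
(which is also what lets a learner tell left from right). Accelerations
are numerical derivatives of the velocities; angular velocity comes from
finite rotation increments; position from velocity integration.

Default study conditions: walk — cadence 120 steps/min, 1.4 m/s, vertical
half-amplitude 0.015 m, duty factor 62% of the stride (double support, no
flight); run — cadence 172, 5 m/s, half-amplitude 0.05 m, duty 35% of
the stride (flight 30% of each step). Mixed trials alternate 40 s blocks
with parameters smoothed over 5 steps at transitions. Duty factor is
expressed as stance/stride (the biomechanics convention) so that the
walk/run semantics above hold.

GRF: per stance, walking uses the two-peak shape sin(πs) + 0.25·sin(3πs)
(peak ≈ 1.05 body weight), running the half-sine sin(πs) (peak ≈ 2.2 BW),
each scaled so the stance impulse equals body weight × step duration —
with two stances per stride this is exactly steady-gait force balance, and
it is what the impulse-conservation test checks by independent quadrature.
The insole stream evaluates the analytic waveform at its native rate
(50/100 Hz); binary contact truth is the stance-interval indicator.

Sensor error model (defaults follow the accelerometer datasheet values):
acceleration gains a ±0.04 mg constant bias, white noise at
0.14 mg/√Hz × √(200 Hz), and a 0.5%-of-16 g-full-scale quadratic
nonlinearity. The fused velocity error is modelled as *bounded and
zero-mean* — a leaky (2 rad/s) integral of the accelerometer noise, slow
GPS-like wander (three sinusoids below 0.2 Hz, amplitudes 6/4/2 mm/s),
and a small broadband term (2 mm/s RMS, low-passed at 15 Hz), clipped at
±0.05 m/s — rather than an unboundedly integrated inertial error, because
the GPS aiding continuously observes velocity. The wander amplitudes
reflect good open-sky conditions (the level-track tests the accuracy
claims refer to); they, the broadband level and the leak rate are our
choices, fixed once. Orientation gets slow small-angle noise at the
datasheet RMS values, angular rate white noise, insole forces 3 N noise.

What the generator does **not** emulate: impact transients and soft-tissue
resonance in acceleration, GPS outages/multipath, inclines beyond a linear
drift, asymmetric or pathological gait, speed-dependent GRF shape changes,
insole drift and saturation. Passing tests therefore demonstrate the
pipeline's correctness and its noise budget under the stated error model,
not field performance on real recordings.

## Problem sizes in the test suite and acceptance script

The accuracy studies run at reduced scale chosen as the package's own
test conditions: segmentation timing on 2×200-step (tests) or 2×500-step
(acceptance script) trials; shift robustness on a 500-step walk and a
1000-step mixed trial; displacement closure on 2×200–300 steps; the
contact/GRF study trains on 300 s (tests) or 600 s (script) of mixed gait
with a 25% held-out tail. All bounds asserted are the original headline
values, never loosened for scale.

## Known limitations

* The zero-velocity dead band (0.02 m/s) assumes the filtered gait signal
  swings well above it; very slow shuffling gait (< ~0.1 m/s vertical
  peak-to-peak) is rejected as irregular rather than segmented.
* Ground track is undefined at standstill and held, so body rotation is
  unreliable across stop-and-go transitions.
* The numpy network trains small models fast on CPU but is not built for
  large architectures or datasets.
* Walking duty factors >100% (contact/step definition) surprise users
  expecting the stance/stride convention; both conventions are documented
  above.
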