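# Methods

## The loop and its assumptions

The simulator implements a single motor-sensory-motor loop in the general
form s = f(m, u), ṅ = g(n, s), ṁ = h(m, n): sensory variables are
memoryless functions of the motor state and the environment (short sensory
time constants), while the neuronal and motor stages carry the dynamics.
The concrete contrast perceiver has one motor variable (pan velocity ω,
deg/s), one neuronal variable (n₁, the integrated ON−OFF event-count
difference in scaled units) and the sensory pair (r_on, r_off).  With the
linear-threshold event sensor the contingency r_on − r_off = C₁γω is exact
(see below), and the chosen g and h make the closed loop a Van der Pol
oscillator in x = √C₄·n₁ with frequency ω₀ = √(C₁C₂γ/C₃).  All loop
constants are positive; the actuator clamps |ω| at `omega_max`.

Assumptions worth keeping in mind: the sensor is 1-D (pan only), noise-free
by default, and linear in luminance change; the loop has no conduction
delays beyond the one-window sensing latency of the engine; the
environment contains exactly one feature (the edge).

## Contrast, luminance and the sensor

Contrast is Michelson contrast with the two half-field levels placed
symmetrically around `mean_luminance`, so the luminance step at the edge is
ΔL = 2γL̄.  A pixel fires one event per `event_threshold` of accumulated
luminance change (a persistent per-pixel reference level, as in a DVS-style
sensor but with a *linear* rather than logarithmic threshold).  An edge
crossing therefore releases ΔL/threshold events of one polarity, and a
sweep at ω crosses ω/pitch pixels per second, giving
r_on − r_off = C₁γω with C₁ = 2L̄/(threshold·pitch) exactly.  A logarithmic
threshold would make the net rate proportional to log(L_bright/L_dark)
instead of γ; linearity in γ is the reason for the linear pixel.

The periodic wrap repeats the dark/bright pattern every 360°, which keeps
an edge available to the sensor during sustained oscillation; the bounded
mode models a finite screen with uniform background outside, so a loop
pointed at nothing stays open (no events, no convergence) — the ex-afferent
loop-opening case.

Defaults: 128 pixels at 0.35°/pixel (≈45° field of view), threshold 0.005
luminance units, 1 ms sampling, jitter off.  Event timestamps are the
sample at which the crossing is detected; sub-sample interpolation is not
performed (the error is bounded by the 1 ms sampling step).

## Default loop constants

The constants are not dictated by the model; they were fixed once so that
the default regime is numerically comfortable and the scales match the
hardware-flavoured story:

* C₁ = 4000/7 ≈ 571.4 events·s⁻¹/(deg/s) — forced by the default sensor
  geometry above with L̄ = 0.5.
* C₂ = π/4000, C₃ = 1/(40π) s — chosen jointly so that ω₀ = 2π rad/s (a
  1 s perceptual cycle) at γ = 0.7 and the motor amplitude there is
  20 deg/s (a few-degree pan excursion, i.e. several pixels).
* C₄ = 4 — puts the n₁ amplitude at 2/√C₄ = 1 in scaled units (n₁ is
  measured in thousands of events; C₂ absorbs the scale).
* μ = 0.3 s⁻¹ — weakly nonlinear (μ ≈ 0.05·ω₀): near-sinusoidal cycles,
  fast convergence, and the small-μ analytics hold to a few permil.
* `omega_max` = 120 deg/s — required because with γ = 0 the motor equation
  ω̇ = μω is divergent; a physical pan unit saturates.

## The engine

Ideal mode integrates the two ODEs with fixed-step RK4 (dt = 1 ms) and the
analytic contingency; the clamp is applied after each step.  Sensor mode
interleaves sensing and acting with a zero-order hold: the camera pans
with the evolving ω, events are collected at every substep, and the rates
measured over one `rate_window` (default 10 ms) drive the *next* window's
Euler substeps — one window of sensory latency, as in a sampled robot
controller.  (Euler inside windows because the held rates are step inputs;
RK4 would buy nothing.)  Replay mode forces ω to follow a recorded trace
and lets n₁ integrate whatever events result: the motor-to-sensory arc is
intact, the sensory-to-motor arc is cut.

The latency has one visible side effect: it acts like a small negative
damping, so sensor-mode cycles are inflated in amplitude (≈30% at the
default window; shrinking the window and threshold removes it, and the
test suite checks that the discrepancy falls monotonically along such a
refinement ladder).  The cycle *period* is much more robust (≈1%), which
is why the decoder works from the period.

Pan azimuth is the trapezoidal integral of the recorded ω — a pure
bookkeeping identity the tests enforce to 1e-9.

## Percept extraction

Cycles are delimited by upward zero crossings of mean-removed n₁ (linear
interpolation between samples).  Each cycle is resampled to a 64-point
phase grid; the convergence residual is the RMS distance between
consecutive cycles in z-scored (n₁, ω) coordinates, which makes the
tolerance (default 0.05) scale-free across contrasts.  The reported period
averages the last three cycle durations for robustness against event
quantisation; amplitudes are half the peak-to-peak range over the final
cycle.  Records with fewer than two complete cycles yield a not-converged
summary rather than an error; constant records are flagged degenerate.

**Decoding.**  γ̂ inverts the small-signal relation γ = C₃(2π/T)²/(C₁C₂)
and is then refined by bisection on the contrast whose simulated
ideal-mode period matches the measured one (18 iterations; the refinement
removes the O(μ²) bias of the small-μ inversion and is what keeps the
sensor-mode recovery error at the percent level).  Decoding refuses
non-converged summaries.

**Confidence.**  C_j is built from the prediction error of the loop's own
internal model, combined over two horizons: (i) one rate-window ahead —
the state is advanced through the loop equations using the recorded
sensory rates and compared with what actually happened; this error is
persistent whenever the motion is decoupled from the sensory stream (the
replay ablation) and near zero in any self-consistent closed-loop run;
(ii) one cycle ahead — the prediction "the loop revisits its state after
one cycle", whose error is large during the transient and decays as the
limit cycle is approached.  A one-step self-model alone cannot express
convergence in ideal mode (the model *is* the generator, so its one-step
error is identically near zero even far from the attractor), which is why
the recurrence horizon is part of the design.  C_j = exp(−e_dyn/σ_dyn −
e_ret/σ_ret) with σ_dyn = 0.05, σ_ret = 0.25 (z-scored error units), is
zero before the first sensory event and capped at 1 − 1e-6 (the loop
approaches, but never reaches, its steady state).  The decision time is
the first crossing of C_d (default 0.9).

**Perceptual ticks** count completed cycles (zero-crossing delimited,
with leading/trailing segments spanning a full period counted as
complete); events within one cycle share a tick.

**Pursuit dwells** are maximal segments (≥ 0.3 s) where |dω/dt|, smoothed
over one rate window, stays below 5 deg/s².  Both settings are exposed in
the analysis config; they were calibrated once on the fixture scenes.

## The fixtures and the study conditions

The canned configs cover: static edges at γ = 0.5 and 0.9 (the
contrast-coding pair), a γ = 0 blank (loop never closes; motor clamps), a
bounded screen with no object in the scanned field (nothing happens at
all), and the moving-edge pursuit experiment.

The pursuit fixture moves the edge as a triangle wave at ±5 deg/s with an
8 s half-period and uses a relaxation-regime parameter set (μ = 10 s⁻¹,
C₃ = 0.005 s, ω₀ = 4 rad/s at γ = 0.7, i.e. μ/ω₀ = 2.5).  The mechanism
behind the dwells is specific to this regime: on the slow branches of the
relaxation cycle the neuronal drive ẋ ∝ (ω − v) stalls exactly where the
pan velocity matches the edge velocity — the retinal slip, and with it the
event stream, vanishes — so the system lingers near ω = ±v and the
occupancy of the phase plane piles up there.  In the default
quasi-sinusoidal regime no such lingering exists and a moving edge
produces no dwells at all; static edges produce no dwells in either
regime (tested), so the dwell detector is specific to stimulus motion.
The residual bias of the dwell velocity (≈ +16% of v at the fixture
settings) comes from the finite slope of the slow branch.

## The replay (open-loop) ablation

"Re-convergence after a perturbation" is probed with a drifting-edge
perturbation: after a closed-loop session on a static edge, the scene is
replaced by one whose edge drifts at 2 deg/s.  The closed loop re-converges
— the neuronal equation forces the mean of ω over a cycle to equal the
drift velocity, so the camera follows the edge and settles on a (moving)
limit cycle.  Replaying the previously recorded motor trace against the
same perturbed scene cannot do this: the recorded ω has zero mean, the
edge recedes through the field, n₁ accumulates a secular drift and the
cycle-to-cycle residual never decays.  A pure contrast switch would *not*
work as the perturbation here: a periodic motor trace driven through a
rescaled contingency produces a rescaled but still periodic n₁, which the
residual cannot distinguish from convergence — the drift is what makes the
open loop fail honestly.

## Numerical choices and limitations

* Fixed-step RK4/Euler only; no adaptive stepping, no delay differential
  terms.  Halving dt moves the ideal-mode period by < 0.05%.
* Determinism: with jitter off every run is bit-reproducible; the optional
  event-time jitter derives its stream from the engine seed.
* Problem sizes: simulations in the tests and the acceptance script use
  20-45 s records at dt = 1 ms (a few tens of cycles), which is ample for
  period estimates at the permil level while keeping any single run under
  a second.
* The synthetic scenes are piecewise-constant luminance fields with a
  single edge; real scenes have texture, photon noise, logarithmic pixel
  response and refractory periods, none of which are modelled.  Passing
  tests therefore validate the loop dynamics and the decoding logic, not
  sensor realism.
* Multi-feature perception (several loops, binding, selection) is out of
  scope; `compose_loop` accepts vector m and n, but the shipped model is
  the one-motor, one-neuron contrast perceiver.
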