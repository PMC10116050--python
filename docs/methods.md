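# Methods

This note documents the models inside `myoreach`, the parameters that matter,
what the synthetic-data generator does and does not emulate, and the design
choices made where the underlying experimental description leaves the design
open.

## Signal chain

All filtering is causal (forward-only), never zero-phase: the controllers are
real-time systems, and the offline path must be sample-for-sample identical
to a streaming one.  `StreamingPipeline` carries second-order-section filter
state across chunks; a dedicated test asserts chunked and one-shot outputs
agree to 1e-9.

* High-pass: 2nd-order Butterworth, 20 Hz cutoff (movement-artifact
  removal).  Coefficients are designed at run time from the sampling rate by
  bilinear transform, so non-1 kHz recordings work; the −3 dB point is
  checked against the analytic response.
* Envelope: full-wave rectification then a 4th-order Butterworth low-pass at
  2 Hz.  The low-pass can ring slightly below zero after sharp offsets; the
  output is clamped at zero because envelopes are amplitude estimates.
* Calibration: the rest level is the mean envelope over the final 3 s of a
  rest recording; the MVC level is the mean over the contiguous 3 s window
  of the MVC recording with maximal summed forearm envelope — the recording
  start is contaminated by contraction ramp-up, and the max-window rule is
  robust to it.  A calibration in which MVC does not exceed rest on some
  forearm channel is rejected with the channel named.
* All envelope arithmetic is in mV; normalisation to MVC happens only inside
  the controllers.

## Direct control

U_e and U_f are the rest-subtracted envelopes of the extensor (ECU) and
flexor (FCU) divided by their MVC envelopes, clamped to [0, 1]; the signed
signal U = U_e − U_f drives the active axis.  Parameters:

| parameter | default | rationale |
| --- | --- | --- |
| deadband | 0.02 MVC | suppresses rest-noise cursor drift |
| cocontraction_threshold | 0.45 MVC on min(U_e, U_f) | see below |
| switch_refractory_s | 0.5 s | one gesture, one toggle |
| trigger_threshold | 0.30 of trigger MVC | trigger channel is quiet otherwise |

The co-contraction threshold deserves a note.  During a braking reversal
(extension → flexion), the 2 Hz envelopes of the two channels cross-fade;
their minimum transiently reaches ≈ 0.33 MVC even though the user never
co-contracts.  A 0.30 threshold therefore fires spurious mode switches; 0.45
sits between the cross-fade peak and the deliberate-gesture level (≈ 0.6).
In the original setting this threshold was tuned per user "to a comfortable
level"; 0.45 is this package's equivalent choice.  The switch is
level-triggered with a refractory interval, and the control output is zeroed
on every tick the switch gesture is active, so switching never drags the
cursor.

The limb-to-cursor mapping presets (`right_handed`, `left_handed`, `dmd`)
follow the study's mapping table; for right-handed users extension is
positive (cursor right on x, down on y), reversed for left-handed and for
the supinated-forearm DMD variant.

## Pattern recognition

Features are computed on high-pass-filtered raw sEMG (the standard input
stage for the Hudgins set), 250 ms windows sliding by 125 ms, five features
× six channels = 30 inputs.  The ZC/SSC deadband defaults to 0.01 mV, the
generator's noise-floor scale.  Features are z-scored with training-set
statistics: waveform length and crossing counts differ by orders of
magnitude, and unscaled features make MLP training erratic.

The classifier is a single-hidden-layer MLP with ten logistic units over
five classes, trained by scikit-learn's lbfgs solver (max 500 iterations,
fixed seed; non-convergence is recorded in metadata, not raised).  Run-time
decoding is an own numpy forward pass from the stored weights, so serialized
models are plain JSON.  The class stream updates every 125 ms with no
majority-vote smoothing; the proportional signal — mean voluntary envelope
over the six forearm channels, normalised to their mean MVC envelope — is
recomputed every 10 ms control tick.  A decoded NO_MOTION forces the output
to zero regardless of the proportional signal.

## Admittance cursor

Per axis, A·v̇ + B·v = F with F = 1 N × U.  The step update is the exact
zero-order-hold solution (velocity: exponential approach to F/B; position:
its closed-form integral), making trajectories independent of the
integration step for piecewise-constant force — a property the tests
exploit.  Presets: healthy A = 6.6e-4, B = 4e-4; DMD A = 5e-4, B = 6e-4
(lower virtual inertia, higher damping; time constants 1.65 s and ≈ 0.83 s).

The raw parameters imply a terminal speed of 1/B = 2500 units per newton
because the original screen units are unspecified.  The workspace is
normalised to [−1, 1]² and both parameters are divided by the same gain so
that full effort yields a configured terminal speed (default 2.0 units/s)
while A/B — the behaviourally meaningful quantity — is preserved exactly.
Positions clamp at the workspace edge with the impinging velocity component
zeroed.  Control tick: 10 ms.

## Synthetic sEMG generator

The signal model is amplitude-modulated band-limited Gaussian noise, the
standard surrogate for surface EMG: per channel, a zero-mean carrier
band-passed to 20–450 Hz is multiplied by channel gain × activation, plus an
independent 0.02 mV RMS noise floor.  Activation comes from commanded
(motion class, intensity) sequences through a 6 × 5 synergy matrix, smoothed
by a 100 ms first-order lag standing in for electromechanical dynamics.
Motion classes admix crosstalk-scaled activity of the other classes; the
co-contraction pseudo-command drives the flexion and extension columns
together; the trigger pseudo-command drives only the trigger channel.

The DMD-like profile scales channel gains to 0.35× healthy, raises crosstalk
from 0.1 to 0.5, and adds a gastrocnemius trigger channel.  These ratios
reproduce the qualitative findings for advanced DMD (much lower absolute
amplitude, less independent activation); they are free generator parameters,
not estimates of any individual.

Calibration kits contain ≥ 4 s of rest, ≥ 4 s of full-intensity
co-activation MVC, and five 2 s repetitions per motion class at
"comfortable" efforts that vary rep to rep (0.5–0.8) — as repeated
comfortable contractions do in practice — which also teaches the classifier
some amplitude invariance.  With 2 s reps, the 250/125 ms windowing yields
15 windows per rep and 375 labelled vectors per kit.

What the generator does **not** emulate: motor-unit structure, fatigue,
electrode shift, impedance drift, inter-channel carrier correlation, or
learning effects across trials.  Passing closed-loop tests therefore shows
that the controllers, dynamics and protocol logic are correct and that the
two control schemes behave plausibly under controlled signal statistics —
not that human performance is predicted.

## Virtual user

The user is a feedback policy evaluated every 100 ms: it computes, per axis,
the force a mass-damper needs to track a desired velocity
v_des = clip(err_pred / t_go, ±v_cap) and brake overshoot,
F = B·v_des + (A/t_brake)(v_des − v), then translates |F| into a commanded
contraction intensity using the control gain it has internalised for its own
profile and method (computable in closed form from the synergy matrix, since
the carrier scale cancels against the MVC normaliser).  Key constants, each
the product of an observed failure mode of naive policies:

* `lead_s = 0.45 s` — err_pred extrapolates the error at the current
  velocity; without anticipating the ~0.5 s envelope-plus-reaction latency
  the loop limit-cycles around the target instead of settling.
* `brake_time_s = 1.0 s` — the inner velocity loop must be slower than the
  actuation latency or it oscillates.
* `vel_tol = 0.03 units/s` — after relaxing, the cursor coasts v·(A/B); the
  user keeps braking until the residual drift fits inside the target.
* `pr_min_intensity = 0.35` — contractions much weaker than the training
  levels decode as rest, so a practiced user keeps commands crisp; below
  this floor the pattern-recognition loop can deadlock just outside the
  target.
* `pr_extra_reaction_s = 0.10 s` — choosing among four discrete gestures is
  slower than modulating a continuous antagonist pair (Hick's law).
* `class_error_rate = 0.02` per decision; `reaction_delay_s = 0.15 s`;
  effort ceiling 0.7 MVC; co-contraction/trigger bursts at 0.6 intensity.

For direct control the policy works the active axis to completion, emits a
switch gesture when the remaining error lies on the other axis, and rests
inside the target.  With these defaults both cohorts complete every trial
well before the 30 s timeout, direct control is reliably faster in the
one-DOF condition (no switch cost, high per-channel gain) and pattern
recognition reliably faster in two-DOF (axis changes are free), across
independent seed batches — the qualitative ordering the task was designed to
probe.  The simulated reaching-time magnitudes fall inside the plausibility
envelopes of published human data without having been fitted to them; they
are properties of this simulator configuration only.

## Analysis

Per (cohort × method × DOF) condition: discarded familiarisation trials and
timeouts are excluded, then mean, sample (n−1) standard deviation, and a
histogram with 1 s bins anchored at 0 are computed.  Timeout failures are
reported as a separate count rather than entering the mean (the human
protocol had no timeouts; exclusion keeps the metric comparable).  For
multi-subject logs, reaching times are first averaged across subjects per
(target, trial index) and the averages pooled — so a ten-subject condition
still yields one event per target presentation — with plain pooling
available as an option.  A healthy condition yields 4 targets × 8 analyzed
trials = 32 events; the reduced DMD protocol yields 16.

## Numerical and degenerate-input choices

* Dwell bookkeeping is strict: any exit resets the 2 s clock; reaching time
  is the start of the completing dwell.
* Session trials are i.i.d. given the seed; the two discarded trials per
  target are kept so event counts match the protocol, but no learning is
  modelled.
* The inter-trial interval is bookkeeping only; the cursor resets to the
  centre instantaneously between trials.
* Simulation sizes in the test suite (batches of 12–20 trials per condition,
  full sessions only where event counts are the point) keep the whole suite
  in the low minutes while leaving the orderings' margins far above their
  run-to-run variability.
* `EmgRecording` rejects non-finite samples, duplicate antagonist roles and
  sampling rates at or below twice the high-pass cutoff; zero-radius or
  overlapping targets and degenerate calibrations are rejected at
  construction.

## Known limitations

* The virtual user is a tuned engineering construct; its parameters shape
  absolute reaching times strongly, and only the relative orderings have
  been shown robust.
* The healthy/DMD amplitude and crosstalk ratios are plausible defaults, not
  measurements.
* Single-subject sessions only; the multi-subject averaging path is
  exercised on synthetic logs rather than simulated cohorts.
* No artifact model (no notch filtering, no adaptive re-baselining) — inputs
  are assumed clean beyond the modelled noise floor.
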