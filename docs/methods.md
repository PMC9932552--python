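# Methods

## Overview

`headingflow` simulates heading perception from optic flow when the
direction of self-motion changes mid-trial. It has three parts: a
synthetic-stimulus generator that renders dense optic-flow sequences for
heading-switch and blackout trials; a simplified competitive-dynamics model
of primate MT/MSTd that turns each flow sequence into a time-evolving
heading estimate; and the bias/precision statistics that quantify how much
the pre-switch heading attracts the final estimate.

## Stimulus model

The observer translates at 1.5 m/s through a rigid cloud of 10,000 dots
filling a box of depths 1.5–9 m and lateral half-width 9 m (enough to fill
the 90° field of view out to the far plane). Heading is an azimuth in the
horizontal plane; a trial holds the pre-switch heading for frames 1–29 and
the post-switch heading from frame 30 (Experiment 1: 34 frames, Experiment
2: 32 frames). One frame is one model time step; the metres-per-frame
displacement uses a 60 Hz frame-rate equivalent, matching a typical display.

A dot at (X, Y, Z) projects to the angular coordinates
(atan(X/Z), atan(Y/Z)), mapped linearly to pixels at 90°/128 ≈ 0.703°/px.
This single equidistant mapping is used everywhere — rasterization,
template placement, decoding — so the stimulus, the model and the readout
share one geometry. Per-dot flow is the exact instantaneous derivative of
the projected position (translation only, no rotation), deposited at the
nearest pixel; co-located dots are averaged and empty pixels stay zero
(roughly 20% of pixels carry a vector; the model's MT pooling densifies
the field). Dots that leave the volume or the near plane are re-spawned
uniformly in the far half of the volume, keeping density stationary.

Two consequences of the equidistant mapping are worth knowing. First, a
translational flow field is exactly radial in gnomonic (tangent-plane)
coordinates but not in angular coordinates: vector directions deviate from
exactly radial by up to ~12° in the far corners (median ~2.5°), though
every vector still points strictly away from the focus of expansion.
Second, the least-squares FoE estimator therefore converts to gnomonic
coordinates before intersecting the flow lines; it recovers commanded
headings to better than 0.05° on noise-free frames (the tolerance we hold
it to is one pixel, 0.8°, at headings up to ±18°).

Blackout frames carry all-zero flow plus an explicit invalid flag, so "no
input" is distinguishable from "zero-motion input".

### Trial grids

Experiment 1 crosses preswitch headings {0, ±6°} with switch angles
{±3, ±6, ±12°} (18 conditions, 10 repetitions differing only in dot
placement) and reads out at frames 32 and 34 — two and four frames after
the switch, the shorter/longer postswitch-viewing analogues. Every switch
condition is paired with a no-switch trial at the same postswitch heading,
trial length and dot placement (same seed), giving the 11 unique no-switch
headings {0, ±3, ±6, ±9, ±12, ±18°}.

Experiment 2 crosses the same 18 heading conditions with four blackout
conditions. No single placement of a one-step blackout within 32 frames
can give both three postswitch flow steps in the mid condition and one in
the post condition, so the schedules are fixed by those constraints
directly: *preblackout* blanks frame 28 (one preswitch frame
between blackout and switch); *midblackout* inserts one blank frame at the
switch, lengthening the trial to 33 frames (readout moves to frame 33 with
it); *postblackout* blanks frames 31–32, so a single postswitch frame
precedes a blackout that runs to the readout — mirroring the human design,
where that blackout persisted almost to the end of the trial. Every
schedule is data, not code: alternative readings are one dictionary edit.

## Neural model

Per frame: each flow component is convolved with a unit-sum 2-D Gaussian
(SD 9.51 px, truncated at radius 6 px; zero padding) — MT spatial pooling.
The pooled field is dotted against 128 radial-expansion templates, one per
pixel column of FoE position along the horizontal midline; template
vectors are unit vectors away from the FoE, weighted by inverse distance
(capped at 1; the FoE row sits at 63.5, between the two middle pixel rows,
so no pixel coincides with an FoE). Negative matches are rectified. The
activation profile is smoothed across templates with a unit-sum 1-D
Gaussian (SD 10.08, radius 19; edge kernels renormalized).

The smoothed drive is temporally averaged, `trace ← c·trace + (1−c)·drive`
with c = 0.7, and fed to a recurrent shunting on-center/off-surround field

    dx_i/dt = −A·x_i + (B − x_i)(I_i + f(x_i)) − x_i · Σ_{j≠i} f(x_j)

with decay A = 0.81, ceiling B = 146 and the faster-than-linear signal
f(x) = x² (configurable), which contrast-enhances winners. The heading is
decoded by population vector, i* = Σ x_i h_i / Σ x_i, over the templates'
preferred headings h_i. On blackout frames the drive is zero and the state
evolves on the recurrent interactions alone.

### Numerical integration

Each stimulus frame advances the field by 10 steps of size dt = 0.1 frame.
The update is a positivity-preserving semi-implicit Euler scheme — decay
and inhibition are treated implicitly,
`x ← (x + dt·B·E) / (1 + dt·(A + E + S − f(x)))` with `E = I + f(x)` and
`S = Σ f(x_j)` — because the explicit form is stiff: with f(x) = x² the
local rate near the ceiling is of order B² ≈ 2·10⁴, far beyond the
explicit stability limit at dt = 0.1. The semi-implicit update agrees with
explicit Euler to O(dt²) per step and keeps every activation in [0, B]
unconditionally, which is also the model's boundedness invariant.

### Drive normalization and operating regime

The raw template dot products have arbitrary units; a single global gain
sets their scale relative to A and B, and the model's qualitative behaviour
lives or dies by it. The gain is expressed as `drive_scale` times a
reference gain (the gain at which a unit-magnitude full-field expansion
about the image center yields peak activation 1). Scanning this constant
with the search module's objective shows three regimes:

- **small scales** (≲ 10³): the recurrent terms dominate; the field locks
  onto a winner within the first frames and the estimate never responds to
  the switch or the blackout — no experiment exists;
- **large scales** (≳ 2.2·10³ at these parameters): the instantaneous
  input dominates; estimates track the stimulus closely, and the
  across-repetition variability collapses to ~0.2°, well below the ~1°
  the repetition noise should produce at this operating point;
- **in between**: winner-dominated evidence accumulation — the estimate
  reflects the accumulated pre-switch evidence, drifts toward the
  post-switch heading as new evidence arrives, and carries ~0.5–1.5° of
  seed-to-seed variability because dot placement perturbs which templates
  win early.

The default, `drive_scale = 2000`, was fixed once from this calibration
(see `calibrate_drive_scale` and `analysis/04_parameter_search.py`) and is
treated as part of the model, not a free parameter. State starts from rest
on every trial; no carry-over between trials.

### Decoding edge cases

Population-vector decoding is undefined on an all-zero state (possible
only before any input has arrived); the decoder raises rather than guesses,
and the experiment runners never read out before frame 2. Whenever total
activation is positive the estimate lies within the template headings'
range by construction.

## Statistics

Heading error is `E = judged − true`, with the postswitch heading as truth.
Heading bias references each switch trial's error to the mean no-switch
error at the same postswitch heading and readout condition, then negates
values from positive switch angles, so positive bias always means
attraction toward the preswitch heading. Condition-level tables report the
mean, a normal-approximation 95% CI over repetitions (descriptive only —
the experiments' conclusions are orderings, not interval tests), and n.
Precision is the sample standard deviation (ddof 1) of the judged heading
across the repetitions of a condition; tables can be collapsed across
angle sign (bias is already sign-normalized, so plain averaging pools
mirror conditions).

## Parameter search

`parameter_search` samples each parameter uniformly from
neurophysiologically motivated intervals (MT radius 2–12.5°, MSTd pooling
radius 7.5–22°, A ∈ [0.1, 1], c ∈ [0.2, 0.8], σ_MT ≤ 28°, σ_MST ≤ 35°,
B ∈ [1, 150]; degrees convert to pixels through the 0.703°/px mapping),
runs a reduced Experiment-1 grid per candidate and scores the bias table.
The default objective encodes the attraction pattern as soft constraints —
positive bias at the early readout, non-decreasing in |switch angle|, not
growing with viewing time — standing in for selection "by eye" against a
target pattern; a squared-distance objective against an explicit target
table is also provided. Diverging candidates score infinity and stay in
the ranking.

## What the synthetic stimuli do and do not capture

The generator reproduces the geometry of the simulated protocols: dense
translational flow, the switch timing, the blackout placements, and
dot-placement-only randomness across repetitions. It does not emulate the
human display (65°×40° viewport, rendered particles with visible size,
60 Hz timing, the ±1° preswitch jitter) nor any perceptual noise source
beyond dot placement. Model precision therefore reflects sampling noise of
10,000 dots only — about 0.5–0.9° per condition here, versus 2–3° for human
judgments — and passing tests say nothing about reproducing human
variability, only about the model's own repetition noise. Observer speed,
depth range and dot recycling are not constrained by the simulation
protocol; the defaults adopt the human-stimulus values (1.5 m/s, 1.5–9 m)
and keep density stationary, and all are exposed in `SceneConfig`.

## Known limitations

- The recurrent-field equations, signal function and the placement of the
  temporal average are fixed here by explicit design choice (the standard
  shunting form with f(x) = x², drive-side averaging); other published
  variants of the model family differ in these details.
- The midblackout condition shows no elevated bias in this model — the
  recurrent field treats it like the no-blackout condition because their
  postswitch viewing matches. That divergence from human judgments is a
  property of the mechanism, reproduced here deliberately, not a bug.
- Bias magnitudes at the default operating point (≈1.3–6° across switch
  angles) sit above the human means (≈1.4–1.7°); the acceptance checks are
  orderings and signs, not magnitude matches, and the search module is the
  tool for tighter quantitative fits.
- Template FoEs sample only the horizontal midline; vertical heading
  components are not represented.
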