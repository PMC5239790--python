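# Methods

## The behavioral model

The model treats intensity matching during movement as a gated
first-order tracking process. The animal marches along the tank
mid-line one pixel at a time (default raster 10 px/cm). At each step:

* **Patch Size Estimation (PSE)** is perfect-knowledge: the width of the
  black band is read from the arena geometry whenever any part of the
  band lies within `[position − rear, position + lookahead]`. The
  forward lookahead defaults to 30 cm. Inside the simulation, `rear`
  equals the sampling area's reach behind the body (19 px ≈ 1.9 cm for
  the default geometry): a patch counts as *identified* until it has
  passed completely out of the visual field, not merely behind the body.
  This convention makes sub-threshold patches elicit exactly zero
  response (while the patch is visible the gate blocks; once it is
  invisible the sampling area is uniform again), and it lets the animal
  brighten back to gray on exit. The standalone `estimate_patch_size`
  helper defaults to `rear = 0` (patch behind the animal → none).
* **CEPS gate**: an identified patch narrower than the threshold blocks
  any reflectance change. The threshold defaults to the animal's mantle
  length, and a patch exactly at threshold opens the gate (inclusive
  `≥`); with mantle lengths of 7.2–12.3 cm this produces the observed
  0% / ~45% / 100% responder pattern at 3 / 10 / 19 cm.
* **If no undersized patch is identified** — including when no patch is
  visible at all — the animal compares its self-reflectance `SR` to the
  mean of the **Camouflage Sampling Area (CSA)** and updates when
  `|SR − CSA|` exceeds a dead band `δ` (default 0.5 percentage points;
  this threshold is a modeling assumption, not an experimentally
  measured quantity). The update is an exponential approach:
  `SR ← SR + g·(CSA_perceived − SR)` with gain `g ∈ [0, 1]`. Observed
  mantle changes (a few percentage points) are far smaller than the
  full 15-point background swing, so partial-gain tracking, not
  instantaneous assignment, is the realistic regime; `g = 1` recovers
  the instantaneous conceptual model.
* **Stochastic behavior factor**: the ±3% factor perturbs the
  *perceived* CSA mean (`CSA_perceived = CSA + η`, `η ~ U(−3, 3)`).
  Applied this way the noise has a bounded stationary effect at any
  gain; added directly to `SR` each step it would accumulate as a random
  walk with variance `≈ η²/(2g)` and dominate the trace at small gains.
  At `g = 1` the two formulations coincide. No-change steps add an
  optional baseline wander `η′ ~ U(−h, h)` (default `h = 0` for pure
  model runs).

### CSA geometry

Only the sampling area's rasterized size (4530 px) is contracted; its
shape in centimeters is unknown. An oval centered on a pixel center
always contains an odd number of pixels (81 odd columns), so the
across-tank center is placed on a pixel *corner* (half-integer row
offsets). A one-dimensional search over the across semi-axis at
along semi-axis 39.5 px gives semi-axes (39.5, 36.5115) px — exactly
4530 pixels. The forward skew defaults to 20 px (anticipation); the
occluded dead zone under the body defaults to empty. Edge handling:
mask pixels falling outside the arena are dropped from the average
(a wall-adjacent view is uninformative), and loading a default geometry
whose count differs from 4530 raises a configuration error.

With full gain the crossing trace equals the CSA column profile, so the
entry ramp spans exactly the oval's along-axis extent (79 px); a
single-column mask reproduces the step function that a pure threshold
rule (no spatial averaging) would produce.

## Synthetic study generator

The generator emulates the study design: 8 animals, one control plus six
dichromic crossings each (patch widths 3, 7, 10, 19, 29, 60 cm in a
200 × 40 cm tank, 18% gray / 3% black), trajectories at constant speed
(8 cm/s with ±25% per-crossing jitter; swimming speed is reported only
qualitatively as slow, so a round value is used) sampled at 0.1 s.
Mantle lengths are drawn from Normal(10.2, 1.2) cm truncated to
[7.2, 12.3].

Published summary statistics are the generating truth for magnitudes:

* **Per-width mean change** follows `0.12·w + 1.72` (percent) for widths
  that can open the gate, and the control mean 1.69% below. At 10 cm
  only a fraction `p = P(mantle ≤ 10) ≈ 0.448` of animals respond, so
  responder amplitudes are mixture-corrected:
  `A(w) = (law(w) − (1−p)·1.69)/p`, which makes the expectation over
  responders and non-responders land on the law.
* **Responder spread**: per-crossing amplitudes are lognormal with mean
  `A(w)` and constant SD 1.73 percentage points, chosen so the pooled
  treatment-group SD reproduces the published ≈ 2.9. The implied
  per-width variance rises steeply between the sub-gate widths
  (≈ 0.34, the baseline-wander variance) and the fully-gated widths
  (≈ 3–3.4, with a mixture bump at 10 cm); the packaged
  4-parameter-logistic coefficients in `calibration.json` describe this
  trend.
* **Control crossings and non-responders** are pure baseline wander: a
  per-step uniform walk whose half-range (0.0424 percentage points per
  pixel step) was calibrated once, by a seeded secant solve, so the
  pipeline's range measure averages 1.69% over control crossings. The
  wander's intrinsic spread gives a control SD of ≈ 0.5. The weak
  corrective pull toward an already-matched background is below
  measurement resolution at calibrated gains, so non-responding
  crossings open the delta band wide rather than mixing frozen and
  wandering steps.
* **Per-crossing gain** for responders is solved by root finding
  (`brentq` on the noise-free amplitude-vs-gain curve, which is exact
  via a first-order IIR filter) so the trace, sampled exactly as the
  pipeline samples it, has the drawn amplitude. Per-animal gain and
  baseline-noise tendencies get lognormal jitter (σ = 0.15) around the
  calibrated values.

What the generator does **not** emulate: pattern/texture responses
(uniform intensity only, as on these uniform backgrounds), velocity–
reflectance coupling (velocity is computed but not coupled), sensor
noise (off by default), lens or illumination artifacts, and any
3-D/water-column optics. Passing tests therefore validate the pipeline's
numerics and the model's logic on intensity traces, not performance on
real footage.

## Extraction

Rendered frames are 8-bit grayscale with nearest-integer quantization;
an 18%-gray card (value 46) sits in a corner of every frame. Extraction
takes the green plane (RGB inputs), balances each frame by the card
(`reflectance = pixel · 18 / mean(card)`, exposure-scale invariant),
tracks the mantle — ground-truth hints by default, emulating the
original manual tracking; a largest-connected-component centroid
detector is available for hint-free stacks — and averages the
1000-pixel (40 × 25) mantle window (columns `center−20 … center+19`,
rows `center−12 … center+12`; the even width needs an explicit
anchoring convention). Quantization bounds the round-trip error at
≤ 0.4 percentage points per sample; in practice ≤ 0.24 for reflectances
up to 18%.

## Transition analysis and statistics

A transition starts at the first sample followed by at least three
consecutive same-sign differences exceeding 0.1 percentage points
(the mechanical form of the original manual three-measurement rule; the
magnitude tolerance is ours, configurable) and ends once the trend fails
for three consecutive differences. Per dichromic crossing at most one
darkening and one brightening segment are kept (largest |Δ| each).
Per-crossing "change in reflectance" is the trace range (max − min) —
the original control-group formula is not stated, and the range makes
control and treatment directly comparable. Slopes are reported against
position (% per cm), matching the positional axis of the crossing
figures.

Group comparison: Kruskal-Wallis (tie-corrected, chi-square
approximation) over control plus the six widths, then pairwise
two-sided Wilcoxon rank-sum tests against control in increasing width
order, uncorrected at α = 0.05 (the most literal reading of the original
procedure; Holm correction is available behind a flag). All pooled
observations identical is defined as H = 0, p = 1. The patch-size
correlation is computed on per-width *mean* changes versus width —
the aggregate relation the trend figure plots; pooling raw crossings
would dilute r with within-width behavioral variance.

## Replicated-study conditions

The reproduction checks run 200 replicated 8-animal studies (seeded;
study seed 2026 in the test suite, user-provided in
`scripts/acceptance.py`) and 500 sampled cohorts for the gate-rate
estimate — enough for sub-percent standard errors on the means while
keeping a full run under a minute. Expected recoveries: control mean
≈ 1.67–1.69%, treatment mean ≈ 4.05%, linear slope ≈ 0.13, per-width
Pearson r ≈ 0.98, modal first significant patch 19 cm (in ≈ 70% of
replicates; the per-animal gate makes ≥ 5 of 8 responders at 10 cm a
~25% event, in which case 10 cm tests significant), and a 10-cm gate
rate of ≈ 44.8% — the exact truncated-normal probability, of which the
published "50%" is the 4-out-of-8 single-cohort observation.

## Known limitations

* PSE is perfect-knowledge; no depth-cue or optic-flow estimator is
  modeled.
* The CSA average is unweighted; a center-weighted variant is plausible
  but unconstrained by the available data.
* The delta threshold (0.5) and the CSA's metric size are conventions.
* The Kruskal-Wallis chi-square p-value is approximate at n = 8 per
  group (the test suite quantifies the gap against a permutation
  oracle); an exact-permutation option exists for the pairwise stage
  via `method="exact"`.
* Transition detection on wandering baselines has a nonzero
  false-positive rate (≈ 0.1–0.3 per crossing at the calibrated
  wander), which inflates responder fractions at sub-gate widths; the
  10-cm responder fraction remains within a 50 ± 15 point band.
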