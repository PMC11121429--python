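# Methods

This note documents the models and numerical choices behind viewfeat:
what each component computes, why its defaults are what they are, and
what the synthetic validation does and does not establish.

## Low-level visual features

All grayscale reductions use ITU-R BT.601 luma (0.299 R + 0.587 G +
0.114 B). Color works in the hexcone HSV model with hue mapped from
the 0–360° wheel to radians in (−π, π], red at 0 and cyan at the ±π
seam.

**Hue statistics are circular.** The mean hue is the angle of the mean
unit vector over chromatic pixels; dispersion is the angular deviation
√(2(1−R)) with R the mean resultant length, which lives in [0, √2] and
matches the magnitudes reported for real window views (≈ 0.8–1.1).
Saturation-zero pixels are excluded — their hue is undefined in the
hexcone model. Two degenerate cases are flagged rather than silently
zeroed: an all-achromatic image (hue undefined) and a near-zero
resultant (antipodal hue mass, mean numerically meaningless; threshold
R < 1e−6).

**Saturation/brightness** are plain means and population SDs of the
unit-scaled planes. Objective brightness is computed but tagged
unreliable in the output flags: across uncontrolled phone photographs
it mostly reflects camera exposure, and the downstream analysis
excludes both brightness features by default.

**Color ratios.** A pixel counts as green (blue) when its hue lies in
[70°, 170°) ([170°, 260°)) and it is chromatic: saturation ≥ 0.15 and
value ≥ 0.10. The sky ratio is computed on a companion image in which
everything that is not sky has been blackened (producing that mask is
manual work outside this package): sky pixels are blue-band or
grey/white (saturation ≤ 0.15 and value ≥ 0.55, for overcast sky),
mask-black pixels (value < 0.02) are excluded, and the denominator is
the full pixel count. None of these thresholds has a canonical value;
all are configurable via TOML.

**Entropy** is the Shannon entropy of the 256-bin luma histogram, in
bits (0 for a constant image, 8 for a uniform histogram). Grayscale
(not per-channel) entropy is used.

**Edges.** Canny on the unit-scaled luma: Gaussian σ = 1.4, hysteresis
thresholds 0.10/0.20 as absolute values on the unit-range gradient
(equivalently, fractions of the maximum possible gradient) — so
low-amplitude texture genuinely falls below threshold instead of being
rescaled into edges. Straight edges come from a deterministic Hough
transform: peaks with ≥ 0.05·diagonal votes propose lines, a line is
accepted if ≥ 0.05·diagonal edge pixels lie within 1 px of it, and its
supporting pixels are marked straight. Non-straight = edge −
straight, so straight + non-straight = overall density is an exact
partition by construction. (Published per-image values from the
original MATLAB tooling do not satisfy this identity, so the two edge
subtypes there overlap or under-cover; the partition convention here
is the cleaner invariant and is documented as a deliberate
divergence.) Edge density is resolution-dependent; an optional
max-dimension-1024 resize flag exists for cross-camera comparability
but is off by default.

**Fractal dimension** is box counting on the Otsu-binarized luma, with
the darker side as foreground (scene structure is typically dark
against bright sky). Box sizes are dyadic, 2 … ⌊min(H, W)/4⌋, on an
origin-anchored grid (a FracLac-style multi-offset minimum-count mode
is available via `box_grid_offsets`); the dimension is the negative
least-squares slope in log–log space. At least 3 box sizes are
required; an empty foreground yields a flagged NaN; estimates outside
[1, 2] carry a warning flag. The counter is verified against an
exhaustive triple-loop oracle, and against analytic cases: filled
plane → 2, straight line → 1, Sierpinski pattern → log 3 / log 2.

**Aggregation** to one vector per participant is the unweighted mean
per feature across that participant's images, with the circular hue
mean averaged as the angle of summed unit vectors; NaN fields (e.g. a
missing sky mask) are skipped per-field.

## Behavioral scoring

**Negative affect.** The 20 STADI state items (anxiety: emotionality +
worry; depression: euthymia + dysthymia; responses 1–4) are summed
after reversing euthymia (r → 5−r), giving a 20–80 composite. The
item→facet layout is configurable; the default assigns items 1–5 /
6–10 / 11–15 / 16–20 to emotionality / worry / euthymia / dysthymia.

**Delay discounting.** Each of 7 delays (0.25, 1, 7, 30, 91, 365,
1825 days — calendar conventions: 1 month = 30 d, 3 months = 91 d)
gets a 6-trial staircase starting at EUR 50 vs EUR 100 delayed. The
offer moves toward indifference by halving steps: ±25, ±12.5, …,
±1.5625 (down after an immediate choice, up after a delayed one).
Halving is the standard titration design and reproduces the task's
two printed worked trials (25 and 75 EUR). The indifference point is
defined as the hypothetical trial-7 offer — the titration's limit —
so an always-delayed responder scores 100·(1 − 2⁻⁷) = 99.21875. AUC
normalizes delays by 1825 and points by 100, anchors the curve at
(0, 1) (the delayed reward is worth face value at zero delay; the
anchor can be disabled), and integrates trapezoidally; it is monotone
in every indifference point.

## Inference

Spearman correlations use average ranks (tie-corrected) with two-sided
p from the t approximation on n−2 df. OLS reports B, SE, t, p,
standardized β = B·sd(x)/sd(y) (sample SDs on the analysis rows after
exclusions), adjusted R², and AIC in the full Gaussian form
n·ln(RSS/n) + 2(k+2) + n(ln 2π + 1), counting the residual variance as
a parameter. The constant shifts all models equally, so selection is
unaffected by the convention; absolute AIC values are therefore only
comparable within a run.

Bidirectional stepwise selection starts from the forced-only model; at
each step every single addition and every single deletion of a
non-forced term is scored, the lowest-AIC move is applied if it
improves on the current model, and the search stops at a local
minimum. Ties within 1e−8 prefer the smaller model, then the earlier
candidate in the declared order; rank-deficient moves are skipped.
The returned trace allows direct verification of local optimality.
AIC-guided selection is known to be liberal (it admits terms with
roughly |t| > √2), so spurious inclusions under the null are expected
behavior, reported rather than suppressed, and no multiple-testing
correction is applied anywhere — matching the procedure this package
reimplements.

Design A (per rating outcome): stage 1 selects among the 12 usable
features; stage 2 forces the stage-1 terms and offers 7 control
variables (age, sex, income, time at home before/during lockdown,
apartment size, image count) to the same search. Design B (per
behavioral outcome): the 7 controls are forced; the stepwise block
offers 7 subjective ratings plus the 12 features. Exclusions: the one
diverse-sex participant is removed from all correlation/regression
analyses (a one-member factor level), then listwise deletion per
analysis; sex is then encoded binary (female = 1) and income as the
ordinal band index 1–7.

## Synthetic data

The generator produces what the original study measured but could not
share. Scenes are schematic: a top sky band (blue gradient or
overcast grey), a warm-grey built background with rectangular facades
and window grids (straight-edge content scaled by `built_density`),
and foliage selected by thresholding multi-octave interpolated noise
so the green pixel count hits the target fraction exactly; the sky
mask blackens exactly the non-sky rows. A per-participant saturation
gain (0.6–1.4) and value gain (0.85–1.15) emulate camera tone
variation between homes — without it, mean saturation is an almost
deterministic function of green fraction, a collinearity that real
photograph sets do not show (objective brightness varying "highly
depending on camera settings" is exactly why the real analysis dropped
it). Renders are deterministic per spec seed, byte-identical across
runs.

Cohorts default to the published study conditions: 110 participants;
image counts from a negative binomial with mean 5.58 and SD 4.01
truncated at 1 (the truncation shifts the realized mean up by ≈ 0.04,
which is accepted rather than recalibrated); demographics sampled
independently from the published marginals (age 26.8 ± 8, income bands,
28:81 male:female) — joint structure is not reported and not modeled.
The three percentage estimates are logistic-normal draws around the
true fractions (log-scale SD 0.35), converted to integers by
largest-remainder rounding so they sum to exactly 100; the 0–100
scales are planted linear responses (e.g. quality on green and sky
fractions, brightness rating on sky fraction) with Gaussian noise,
clipped. Outcomes: negative affect = 58 − 0.12·brightness_rating +
N(0, 5.5²), rounded and clipped to [20, 80], realized as 20 item
responses that sum to the composite exactly (items nudged point by
point; euthymia stored un-reversed); discounting by a hyperbolic agent
with log₁₀ k ~ N(−2, 0.8) choosing delayed iff 100/(1 + kD) ≥ offer
(ties toward delayed). One diverse-sex participant and 2/1 missing
negative-affect/AUC outcomes are injected so the analysis reproduces
the reference bookkeeping (110 → 109 → 107 for the negative-affect
model).

**What passing tests show — and don't.** Recovery on this generator
demonstrates that the pipeline is internally consistent: the extractor
measures what the renderer painted, the scorers invert the planted
response models, and selection finds planted predictors at realistic n
and noise. It does not show that the features capture what humans
perceive in real views: schematic scenes lack ephemeral content
(clouds, weather, people), perspective, occlusion by curtains or
frames, camera optics, and the semantic texture of real vegetation.
Correlations on synthetic cohorts (e.g. ρ ≈ 0.9 between green ratio
and perceived % nature) are accordingly much stronger than the ≈ 0.5
reported for real data; only signs and structure, not magnitudes, are
meaningful comparisons.

## Problem sizes and determinism

Default scenes render at 128×128: features of interest (band
fractions, straight/non-straight edge content, fractal texture) are
scale-stable, and this keeps a full 110-participant, ~600-image
pipeline run at well under a minute. Every random quantity flows from
an explicit integer seed; the CLI derives per-stage seeds as
CRC32(master_seed:stage), so stages rerun independently yet
reproducibly, and repeated runs produce byte-identical artifacts.

## Known limitations

* Straight-edge assignment uses infinite Hough lines gated by pixel
  support, not true segment extraction; collinear but separated edge
  fragments can be jointly credited as one line.
* Otsu binarization makes the fractal dimension sensitive to global
  lighting; FracLac's exact binarization/grid scheme is not public, so
  absolute FD values are convention-dependent (the multi-offset mode
  narrows, but does not close, that gap).
* The staircase's indifference point is the titration limit; with 6
  trials it quantizes indifference to a 0.78125-EUR grid.
* Stepwise inference inherits AIC's liberality and post-selection
  p-values are not corrected; they should be read descriptively.
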