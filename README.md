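# viewfeat

Quantifying what people see out of their windows, and what that view
may do to how they feel.

Residential window views are a plausible everyday exposure for mental
health: more natural views are thought to support affect and
self-regulation. Because "naturalness" is hard to measure objectively,
one line of work describes view photographs by **low-level visual
features (LLVFs)** — pixel statistics computed without any object
recognition — and relates them to subjective ratings and behavioral
outcomes. This package implements that measurement pipeline end to
end:

* **14 LLVFs per image** (`viewfeat.image_features`): circular hue
  mean and angular deviation (hue in radians, red = 0, cyan = ±π, SD =
  √(2(1−R)) with R the mean resultant length), mean/SD saturation and
  brightness, green and blue pixel ratios (hue-band classifiers),
  sky pixel ratio from a companion image with non-sky blackened,
  gray-level Shannon entropy (0–8 bits), Canny edge density split into
  straight and non-straight parts by a Hough line detector (the split
  is an exact partition), and a box-counting fractal dimension
  (−slope of log N(s) vs log s on the Otsu-binarized luma). Features
  are averaged per participant across their window images (hue
  circularly).
* **Behavioral outcomes** (`viewfeat.behavioral`): the state
  negative-affect composite of the 20-item STADI state scale (euthymia
  reversed, range 20–80) and delay discounting from an adaptive
  staircase — EUR 50 now vs EUR 100 later, offer titrated by halving
  steps over 6 trials at each of 7 delays (6 h … 5 y), indifference
  points taken as the titration limit, and the normalized trapezoidal
  area under the indifference curve (AUC ∈ [0, 1], anchored at (0, 1);
  higher = less impulsive).
* **Inference** (`viewfeat.stats`): tie-corrected Spearman correlation
  matrices; OLS with raw B, SE, standardized β, t, p, adjusted R², and
  full-Gaussian AIC; bidirectional stepwise selection by AIC with
  forced-entry blocks; the two hierarchical designs (ratings ←
  features, then controls; outcomes ← forced controls + stepwise view
  parameters) with the exclusion rules (diverse-sex participant
  removed, per-analysis listwise deletion).
* **Synthetic cohorts** (`viewfeat.synthetic`): because real view
  photographs are privacy-protected, validation runs on schematic
  scenes (sky band, rectilinear buildings, fractal-noise foliage) with
  exactly known sky/green/built fractions, and cohorts with planted
  rating and outcome models, published demographic marginals, and the
  study's injected exclusions.

## Worked example

The numbered scripts under `analysis/` run the full study pipeline on
the default synthetic cohort (110 participants, ~5.6 images each):

```sh
python analysis/01_simulate_cohort.py     # scenes, ratings, outcomes
python analysis/02_extract_features.py    # 14 LLVFs per image
python analysis/03_score_outcomes.py      # STADI + staircase scoring
python analysis/04_correlations.py        # Spearman matrix
python analysis/05_stepwise_models.py     # stepwise designs A and B
```

A run prints, among other things:

```
participants: 110  images: 643 (mean 5.85 per participant)
green_ratio vs true green fraction: r = 1.000
negative affect recovers planted composite exactly: 100%
Spearman rho(AUC, planted k) = -1.000 (should be strongly negative)
  rho(green_ratio, pct_nature) = +0.89  (p = 1.1e-38)
  rho(sky_ratio, pct_sky) = +0.83  (p = 4.1e-29)
N = 110 -> 109 after diverse-sex exclusion; per-model N:
  {'pct_nature': 109, ..., 'negative_affect': 107, 'auc': 108}
pct_nature: stage 1 selected ('green_ratio', ...) 
planted green -> %nature recovered positive: True
planted brightness -> negative affect recovered negative: True
```

That is, the extractor recovers the generator's true scene fractions,
the staircase scoring recovers the planted discount behavior, the
exclusion bookkeeping matches (110 → 109 analyzed; 107 for the
negative-affect model), and the stepwise designs recover the planted
effect signs.

The same pipeline is available as a CLI over any dataset laid out as
`cohort/<participant>/window_<j>.png` (+ `_skymask.png` siblings):

```sh
viewfeat --config run.toml --seed 3 all
viewfeat --config run.toml report
```

Coefficient tables are written one CSV per model (Variable, B, SE,
beta, t, p, adjusted R²) plus a JSON selection trace recording the AIC
at each stepwise move.

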