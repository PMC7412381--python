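# Methods

## Segmentation model

The segmentation statistic is GMR, the per-pixel difference between the
green and red channel digital numbers (DNs) of an 8-bit RGB photograph.
Green vegetation reflects more in the green band than the red; soil and
water have nearly equal green and red DNs. A pixel is canopy iff
GMR > threshold, with strict inequality — pixels exactly at the threshold
are background. The default threshold is 10 DN; 30 is kept available
because it visibly removes darker canopy regions and is useful for
sensitivity checks. "Reflectance" here means raw DNs: no radiometric
calibration, white-balance correction, denoising, smoothing or cropping is
applied, and frames are processed whole, because the measurement protocol
being modelled applies none of these. Canopy cover is the pixel fraction
CC = N_plant / N_total.

Assumptions and limits: the threshold rule fails on shadowed canopy, whose
GMR drops below 10 even though the pixels are leaf. This is a property of
the method, not a bug; the synthetic renderer reproduces it deliberately
(below), and no shadow-aware correction is attempted.

## Feature model

Ten vegetation indices (INT, NBI, NGI, NRI, GRRI, GBRI, NGRDI, NGBDI, EXG,
VDVI) are scalar functions of the mean R, G, B DNs of a pixel set. The
canonical path is means-first: compute channel means once per image, then
apply each formula once. A per-pixel variant (formula per pixel, then
average) exists behind `compute_vi_per_pixel` for sensitivity analysis
only; the two differ for the ratio-form indices on heterogeneous pixel
sets. Indices are computed before segmentation (all pixels) and after
(canopy pixels only); CC exists only after segmentation, so the feature
vector has 21 entries. Undefined values (zero denominators, empty canopy)
are reported as missing (NaN), never fabricated or silently infinite, so a
batch over many images completes and reports which images failed which
index.

## Agronomic aggregation

Each plot is observed at four stages: tillering, jointing, heading,
filling. Canopy structure peaks at heading, so heading-stage values
(LAI_HS, PH_HS, CVP_HS) and four-stage arithmetic means (LAI_avg, PH_avg,
CVP_avg) summarise a plot. CVP_avg is the mean of the per-stage CVPs, not
lai_avg × ph_avg. Yields are grouped per variety type with half-open
intervals — type A: low < 7500 ≤ middle < 8500 ≤ high; type B:
low < 6500 ≤ middle < 7500 ≤ high (kg/ha) — lower bound inclusive so the
line is partitioned and levels are monotone in yield. Correlations are
Pearson (signed r with p < 0.01 flags matches how such analyses report
linear association; Spearman is available behind a flag). Units: PH is in
metres, keeping CVP in the working range ~0–5 given LAI up to ~7.

## Exponential CC–CVP fit

CVP = a·e^(b·CC) is fitted by nonlinear least squares on the original
scale (scipy `curve_fit`), initialised from the log-linear regression of
ln(CVP) on CC. The log-linear initialiser alone would minimise
multiplicative error; refitting on the original scale matches the
least-squares convention of the curve being modelled. R² is 1 −
SS_res/SS_tot against the fitted curve. Non-convergence raises an error
carrying the initialiser's parameters. Fits are per variety by default
(each variety has its own leaf architecture and hence its own CC–CVP
curve), with a pooled option.

## Random-forest prediction

Predictors are the features with |r| ≥ 0.5 Pearson correlation against
CVP. The threshold is inclusive and on the absolute value: the published
correlation table retains features at r = 0.50 and r = −0.50, and
intensity-type indices enter negatively. Constant feature columns are
excluded with a warning. The forest is scikit-learn's
`RandomForestRegressor` with ntree = 500, mtry = ⌊p/3⌋ (minimum 1; 3 for
the ten standard predictors) and the run seed; bagged trees with
per-split feature subsampling, prediction = mean over trees.

The 7:3 split (168/72 at n = 240) is stratified by variety × growth stage
by default — pooled evaluation across unbalanced groups would otherwise be
seed-fragile — with a plain random option. GPM and LPM reuse the same
seed-derived partition so their comparison is paired. LPM trains one model
per variety and concatenates per-variety validation predictions before
computing pooled R²/RMSE (not a per-group average). Modelling-set metrics
are resubstitution and labelled as such in reports. R² is not clamped and
may be negative. Relative GPM→LPM changes are reported to one decimal:
(new−baseline)/baseline·100 for improvements, (baseline−new)/baseline·100
for decreases.

## Synthetic generator

The generator emulates a two-site trial: each site grows one type-A
variety (SJ18, SJ6 — long, loosely packed leaves, taller, higher yield)
and one type-B variety (LY16, WYD4 — short compact leaves, lower yield),
under nitrogen rates {0, 79.1, 90.5, 102.3, 115} kg/ha × 3 replicates,
sampled at four stages: 30 plots per site, 60 plots, 240 stage-samples.

Growth: LAI = lai_max × stage shape × N response × lognormal noise, PH
analogous. Stage shapes (LAI: 0.35, 0.75, 1.00, 0.85; PH: 0.55, 0.80,
1.00, 0.95) peak at heading. The nitrogen response is saturating and
multiplicative, resp(n) = 0.55 + 0.45·(n/115)^0.7, chosen so the five
rates spread plots across all three yield levels. The functional form is
invented; it is constrained only to reproduce the qualitative shapes
(heading-stage peak, monotone N response) and is fully parameterised so
tests can pin it. Defaults lai_max 4.8–5.8, ph_max 0.80–0.95 m keep CVP in
the 0.2–5 working range. Noise is lognormal with σ = 0.1 on LAI and PH.
Yield = intercept + slope × CVP_avg + Gaussian noise (σ = 250 kg/ha),
type A: 5200 + 1100·CVP_avg, type B: 5300 + 950·CVP_avg, calibrated once
so type-A plot yields straddle the 7500/8500 cut points and type-B the
6500/7500 ones.

Per-sample cover targets come from inverting the variety's CC–CVP curve
(defaults: the published per-variety (a, b) fits), clipped to [0, 0.98],
so synthetic data live on the published CC–CVP manifold. All randomness
flows from one master seed through named substreams (growth, yield,
render), so any stage is independently reproducible from the manifest.

Rendering: leaf-shaped ellipses (type A long axes 8–18 px, type B 4–9 px
at the default 192×108 frame, a 1/10 linear scale of 1920×1080 chosen so
the 240-frame pipeline runs in seconds; full scale is a config option) are
scattered over a soil background until the truth mask matches the target
cover to within one pixel; single-pixel top-up handles the last fraction.
Palette guarantees: lit canopy G − R ∈ [45, 105], soil |G − R| ≤ 5, so
with no shadows segmentation at threshold 10 recovers the truth mask
exactly. A `shadow_fraction` of canopy pixels is darkened to
G − R ∈ [0, 8] — below threshold but still canopy in the truth mask —
emulating bottom-leaf shadowing. In the image pipeline the shaded fraction
scales with true cover, so measured CC undercounts closing canopies and
the CC–CVP scatter flattens at high cover.

Fast mode emits feature vectors without rasterising: channel means are a
mixture of lit-canopy, shadowed-canopy and soil colour components weighted
by true cover (shaded weight ∝ cover², giving the same saturation), with
measured CC = lit fraction plus N(0, 0.01) jitter. What the generator does
not emulate: camera optics, JPEG artefacts, illumination variation,
specular water surfaces, panicle colour at filling, or 3D plant
architecture — so passing tests demonstrate correctness of the method's
arithmetic and its qualitative behaviour under the modelled mechanisms,
not field-level accuracy.

## Local vs global modelling on synthetic data

With the published per-variety curves as defaults, the between-variety
spread in b (3.62–3.87) is small: at equal cover, predicted CVP differs by
only ~15–25% across varieties, comparable to the generator's measurement
noise. At n = 240, LPM's smaller per-variety training sets (42 samples)
offset that weak heterogeneity, and GPM and LPM validation R² are
statistically indistinguishable (differences within ±0.03, sign varying
by seed). The local-beats-global property is therefore exercised where it
is identifiable: a variety-heterogeneous configuration with b spread over
2.8–4.9 (the generator's heterogeneity knob), where LPM wins in 10/10
seeds; conversely, identical curves make GPM ≈ LPM within 0.05. The
defaults themselves were not tuned.

## Numerical choices and degenerate inputs

- Strict inequality in segmentation; threshold validated to [−255, 255].
- GMR is computed in int16; no clipping of negative differences.
- Splits: train size = round(n × ratio), clamped to [1, n−1]; stratified
  allocation uses largest-remainder rounding of per-stratum quotas.
- `cvp = lai × ph` holds exactly on construction; records re-read from
  text are accepted within 1e−9 relative tolerance to absorb decimal
  rounding.
- Correlation requires ≥ 3 points and nonzero variance; constant inputs
  raise a degenerate-input error (feature selection downgrades this to a
  warning and exclusion).
- Exponential fits require positive CVP; constant data yield a = c, b = 0.
- Rendering raises after a bounded number of placement attempts if the
  target cover is unreachable.
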