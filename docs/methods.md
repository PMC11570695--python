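# Methods

## The measurement model

The GOD/POD reaction converts glucose into a pink quinonimine complex whose
absorbance grows linearly with concentration. The generator renders this as
per-channel Beer–Lambert transmittance of a white polyvinyl-film background:

    I_k(c) = round( background_k · 10^(−ε_k · ℓ · c) ),   k ∈ {R, G, B}

with absorptivities ε = (0.0005, 0.004, 0.0015) per mg/dL, path multiplier
ℓ = 1, and background (225, 221, 219). Green dominates because a pink
product transmits red and absorbs green. The green absorptivity 0.004 is
the separability optimum: the total green span over 50–200 mg/dL,
`bg·(10^(−50a) − 10^(−200a))`, is maximized at a = log10(4)/150 ≈ 0.004
(about 47 % of the 8-bit range — no absorptivity can reach more, since
higher values compress the high-concentration end faster than they spread
the low end). The weakest adjacent-class color gap is therefore at
200 mg/dL (~3–4 gray levels), and that is exactly where residual
classifier confusions concentrate.

No published RGB measurements exist for this assay at known
concentrations, so the color scale is constructed from the proportionality
law, not fitted; absolute synthetic colors are not claims about any real
device.

## Scene, illumination, and noise

Each capture is a centered well disc (radius 0.28 × image side) of the
assay color, ringed by a dark rim (intensity 30, width 0.05 × side) — the
cut channel contour of the film device — on the white film background
(intensity 220). Conditions act multiplicatively per channel:

- lighting: natural = gain 0.9 with warm tint (1.03, 1.0, 0.95),
  artificial = gain 1.0, neutral;
- location 1/2/3 = gain 0.9/1.0/1.1 (±10 % room-position brightness);
- camera white-balance gains per phone profile (three profiles mirroring
  the capture campaign's handsets, nominal sensor resolutions recorded in
  the manifest; rendering is at 400 × 400 since the downstream resize makes
  native scale irrelevant);
- additive Gaussian sensor noise (default σ = 3 intensity units per
  camera profile), rounded half-away-from-zero and clamped to [0, 255].

Two scene constants are deliberate. First, all base intensities sit below
255 / (max combined gain ≈ 1.13), so the brightest condition never clips:
smartphone auto-exposure keeps the white film inside the sensor's dynamic
range, and a clipped film would silently break the illumination-cancelling
property of the contrast stretch. Second, the dark rim anchors the low
quantile of every image. With rim and film present, the 1 % stretch maps
[rim·g, film·g] onto [0, 255] for any scalar gain g, cancelling
illumination exactly while preserving the well's relative intensity — the
concentration signal. Without such a dark anchor the stretch would map
(well, film) to (0, 255) in every image and erase the signal entirely.

Per-image seeds derive deterministically from the master seed and the
factorial cell indices via `numpy.random.SeedSequence`, so any subset of
the campaign regenerates bit-identically.

What the generator does **not** emulate: lens vignetting and radiometric
falloff, JPEG compression, chemistry kinetics and incubation-time
variation, hematocrit effects, well-localization error, and the
heavy-tailed condition diversity of hand-held capture. Passing tests on
synthetic data therefore demonstrate that the pipeline's machinery is
correct and recovers a Beer–Lambert signal under multiplicative condition
variation — not that the trained network would meet the same accuracy on
physical captures.

## Preprocessing

1. Grayscale: ITU-R BT.601 luma, `round(0.299 R + 0.587 G + 0.114 B)` —
   the default of the common imaging toolchains.
2. Contrast stretch: linear-interpolation quantiles over the pixel
   multiset at the 1 % and 99 % points; pixels at or outside the quantiles
   saturate to 0/255, the interior maps linearly. Computed per image (the
   single-photo point-of-care workflow), not per dataset. Constant frames
   pass through unchanged with a warning rather than erroring.
3. Resize to the classifier input (100 × 100 by default) by bilinear
   interpolation with half-pixel-center alignment; nearest-neighbor is
   available for ablation. Every stage rounds half-away-from-zero back to
   8-bit integers, keeping the chain's contract explicit.

## Classifier

Architecture: input → [conv → ReLU → batchnorm] × 2 → optional
channel-wise softmax normalization stage → flatten → dense (+ dropout) →
dense(16) → softmax. The channel softmax rescales feature maps so channel
activations at each spatial location form a probability vector; it is kept
on in the default profile for architectural fidelity and off in the small
profile, where it slows convergence without benefit.

Default profile: 100 × 100 × 1 input, 16 then 32 filters (3 × 3, stride 1,
same padding), one 256-unit dense layer, dropout 0.5, giving a closed-form
trainable count of 81.9 M — the flatten→dense edge dominates, which is how
a two-block network exceeds 75 M parameters. Small profile: 32 × 32 input,
16/32 filters at stride 2, one 128-unit dense layer, no dropout, ~270 k
parameters. The trainable count has the closed form
Σ conv (k²·c_in + 1)·c_out + Σ batchnorm 2c + Σ dense (n_in + 1)·n_out and
must equal the total size of the allocated parameter arrays.

Training is mini-batch Adam (β = 0.9/0.999) on cross-entropy, with four
conditioning measures that matter on this data regime, where every image
is the same scene and the between-class signal is a small intensity shift:

- **mean-image centering** — inputs are centered by the training set's
  mean image. Without it, the shared background pattern dominates every
  activation; dense units are then all-on or all-off across the whole
  dataset and most die in the first epoch;
- **warmup + cosine decay** — 20 linear warmup steps, then cosine decay to
  zero over the configured epochs; the decaying tail is what converts
  late-training oscillation into accuracy;
- **global gradient-norm clipping** (ceiling 1.0) — permits the relatively
  high peak learning rate the short schedule needs;
- **batch-norm recalibration** — after the last epoch, running statistics
  are replaced by exact training-set moments in one forward pass; the
  momentum-averaged estimates lag the weights badly on short schedules.

Optionally (`restarts > 1`, used by the small profile with 3) training is
run from several seeded initializations and the run with the lowest final
*training* loss is kept — multi-start selection on the training objective
only, the same guard against bad basins that clustering implementations
apply; the held-out set plays no role in the choice.

Splitting is stratified by class (80/20 by default, seeded); k-fold
cross-validation uses stratified folds, trains one model per fold and
pools one confusion matrix in which every item is predicted exactly once.
Inference is deterministic: dropout off, running batch-norm statistics,
argmax ties broken toward the lowest class index.

## Evaluation

One-vs-rest counts come from the pooled confusion matrix: TP is the
diagonal entry, FP the column remainder, FN the row remainder, TN the
rest. Precision, recall and F1 follow the standard ratios with
zero-denominator metrics defined as 0 (not NaN) so macro averages stay
computable; summary precision/recall/F1 are macro averages over the 16
classes.

ISO 15197 bands: a prediction is acceptable within ±15 mg/dL when the true
value is below 100 mg/dL and within ±15 % at or above it, boundaries
inclusive; the two rules coincide at exactly 100 mg/dL, so the band is
continuous there. The predicted concentration is the numeric value of the
argmax class (classification, not regression). R² is computed against the
identity line, 1 − Σ(pred−true)² / Σ(true−mean(true))², separately for the
low and high strata; a stratum with fewer than two distinct true values
reports no R². The fitted-regression-line convention (squared Pearson
correlation) is available behind `r2_mode="fitted"`.

## Problem sizes and numerical choices

The small profile — the package's standard desk-scale study — uses 16
classes × 12 images (2 lightings × 3 locations × 1 camera × 2 replicates)
rendered at 64 × 64 with sensor noise σ = 1, preprocessed to 32 × 32, and
15 training epochs at batch size 8, learning rate 10⁻², 3 restarts: about
seven seconds end to end on one CPU core. Under these conditions held-out
accuracy across seeds falls in 0.92–1.00 with ISO compliance 1.0 (the rare
adjacent-class confusions at the high-concentration end are within band),
and a label-permutation control trains to chance-level accuracy (1/16).
The full-scale defaults (1440 images at 400 × 400, the 81.9 M-parameter
network, 35 epochs, 10-fold cross-validation) are configured but are a
compute-scale choice, not a different code path.

Numerical conventions worth naming: float32 parameters and activations in
the network; round-half-away-from-zero at every 8-bit boundary;
`SeedSequence`-derived integer seeds everywhere randomness enters (weight
init, shuffling, dropout, splits, folds, per-image noise), making every
run — including the pipeline's artifact files — bit-reproducible for a
given (config, seed).

## Known limitations

- The synthetic color scale is constructed, not fitted to measured assay
  colors; absolute accuracies on synthetic data do not transfer to
  physical captures.
- The classifier treats concentration as purely categorical; no ordinal
  structure is exploited, although the evaluation layer scores the numeric
  consequences (ISO bands, R²).
- The inter-block channel softmax is faithful to the described
  architecture but unusual; with it enabled, training needs more epochs
  than the small profile budget.
- Per-image contrast stretching assumes some dark anchor exists in the
  frame (here the device's rim); frames without one lose the absolute
  intensity signal by construction.
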