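# glucopipe

Smartphone colorimetric glucose quantification, end to end and fully
reproducible.

In a GOD/POD (glucose oxidase / peroxidase) assay, glucose in a sample
drives the formation of a pink quinonimine complex whose absorbance is
directly proportional to glucose concentration (Beer–Lambert). A phone
photo of the reaction well therefore carries the concentration in its
color, and a compact 2-D CNN can read it out as one of 16 discrete levels
(50–200 mg/dL in 10 mg/dL steps) — a camera-only alternative to a glucose
meter for point-of-care use.

The package is aimed at researchers building or validating such
camera-based colorimetric readouts. It provides:

- **`glucopipe.synthetic_imaging`** — a seeded Beer–Lambert well-image
  generator. Per channel $k$, a concentration $c$ renders as
  $I_k(c) = I^0_k \cdot 10^{-\varepsilon_k \ell c}$ with the green channel
  absorbed most (pink product), modulated by a factorial capture campaign:
  2 lighting conditions × 3 locations × 3 camera profiles × 5 replicates
  over 16 concentrations = 1440 labeled PNGs in folder-per-class layout.
- **`glucopipe.preprocessing`** — the three-stage chain: BT.601 grayscale,
  contrast stretch saturating the bottom and top 1 % of pixel values, and
  bilinear resize to 100 × 100.
- **`glucopipe.cnn`** — a pure-numpy CNN (two conv–ReLU–batchnorm blocks,
  optional channel-softmax normalization stage, dense + dropout + softmax)
  with Adam training, stratified 80/20 splitting and stratified k-fold
  cross-validation. The default profile has > 75 million trainable
  parameters; a ~270 k-parameter small profile trains in seconds on a CPU.
- **`glucopipe.evaluation`** — per-class precision / recall / F1 from
  one-vs-rest confusion-matrix counts
  ($P = \frac{TP}{TP+FP}$, $R = \frac{TP}{TP+FN}$, $F1 = \frac{2PR}{P+R}$,
  accuracy $= \frac{TP+TN}{TP+TN+FP+FN}$), ISO 15197 accuracy bands
  (±15 mg/dL below 100 mg/dL, ±15 % at or above, 95 % pass level), and the
  coefficient of determination against the identity line, stratified into
  low (< 100) and high (≥ 100 mg/dL) ranges.
- **`glucopipe.pipeline` + the `glucopipe` CLI** — configuration, dataset
  IO, and the orchestrated generate → preprocess → train → evaluate run.

## Worked example

```python
from glucopipe.pipeline import RunConfig, run_pipeline

summary = run_pipeline(RunConfig.small_profile(seed=1), "runs/demo")
print({k: summary[k] for k in
       ("accuracy", "compliance_fraction", "r2_low", "r2_high")})
```

This generates 192 synthetic captures (16 classes × 12 low-noise images at
64 × 64), preprocesses them to 32 × 32, trains the small CNN for 15 epochs
on a stratified 80 % split, and evaluates the held-out 20 %. It finishes in
under ten seconds on one CPU core and prints:

```
{'accuracy': 1.0, 'compliance_fraction': 1.0, 'r2_low': 1.0, 'r2_high': 1.0}
```

Every held-out image was assigned its true concentration, so 100 % of
predictions fall inside the ISO 15197 bands and the predicted-vs-true
scatter lies exactly on the identity line in both concentration ranges.
Across other seeds the held-out accuracy typically lands between 0.92 and
1.00, with the rare confusions confined to adjacent classes at the high
end of the range, where Beer–Lambert attenuation compresses the color
differences — those errors stay within the ISO bands.

The run directory is self-describing: `provenance.json`, `manifest.csv`,
`history.csv` (loss curves), `confusion_matrix.csv`, `metrics.csv`, and
`iso_report.json`. Rerunning with the same config and seed reproduces
every artifact byte for byte.

The same thing from the shell:

```bash
glucopipe run --small --seed 1 --out runs/demo
glucopipe generate --out data/full --seed 7          # full 1440-image campaign
glucopipe crossval --data data/full --k 10 --out runs/cv
```

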