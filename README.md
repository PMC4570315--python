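# vinotaste

Colorimetric taste-sensor simulation and chemometrics for white wine.

An electronic-tongue approach to wine tasting: an 8-well array of
dye-bead conjugates (alizarin, calconcarboxylic acid, cresol red,
crystal violet, fluorescein, methylthymol blue, phenol red, xylenol
orange) changes colour when a wine sample is loaded, a camera photographs
the chip before and after, and the 24 per-well RGB differences
(8 dyes x 3 channels) form a fingerprint of the wine's taste chemistry.
`vinotaste` implements the full downstream analysis — and, because no
public dataset of such measurements exists, a ground-truthed synthetic
front end that emulates the bench:

- **synthetic data** — 23 base wines + 22 pairwise blends with a
  two-cluster (sweet/dry) concentration structure over 11 taste
  chemicals; Langmuir-saturating dye colour responses
  `Δ = Σ_c S_c · conc_c/(conc_c + K_c)`; rendered before/after well-plate
  images with camera noise; Gaussian-peak absorbance spectra.
- **taste scores** — sweetness `0.75·glucose + 1·sucrose + 1.5·fructose`
  (mg/L), sourness `Σ acid conc / molar mass` (mmol/L), astringency in
  tannic-acid equivalents via a Folin–Ciocalteu standard curve
  (absorbance `A = −log₁₀ T` vs ppm, inverted and dilution-corrected).
- **image colorimetry** — well detection (background thresholding,
  connected components, circularity filter), after-minus-before mean RGB
  per well, and band-averaged absorbance (red 620–780, green 500–580,
  blue 450–500 nm) vs concentration R².
- **chemometrics** — mean-centred PCA with explained variance, scores,
  loadings, and PC1–PC2 / PC1–PC3 score plots.
- **neural networks** — a from-scratch feed-forward engine with four
  trainers (incremental, batch, iRPROP−, QuickProp) and five activations
  (sigmoid, linear, gaussian, sin, cos), finite-difference-verified
  gradients.
- **model selection** — 35/10 calibration/test split (calibration split
  7:3 into training/validation for early stopping), configuration grid
  search, ranking by R² with RMSEP = `√(Σ(k_E − k_P)²/N)` as tie-breaker,
  and RMSEP as a percentage of the target range.

## Worked example

```sh
vinotaste run --seed 1 --out demo_run
```

runs simulate → extract → score → pca → train → report and writes every
intermediate (panel CSV, PNG image pairs, features CSV, scores CSV, PCA
tables and plots, per-taste leaderboards, measured-vs-predicted scatter
plots) plus a seed-recording manifest. The same run from Python:

```python
from vinotaste.pipeline import RunConfig, run_pipeline
run_pipeline(RunConfig(out_dir="demo_run", seed=1))
```

With seed 1 the report (`demo_run/report.json`) contains:

| taste       | best configuration                        | test R² | RMSEP  | RMSEP % of range |
|-------------|-------------------------------------------|--------|--------|------------------|
| sweetness   | quickprop, lr 0.9, 9(sigmoid)-11(gaussian), sin out | 0.992  | 4052   | 3.63 |
| sourness    | incremental, lr 0.9, 9(sigmoid)-11(sigmoid), sin out | 0.964  | 36.2   | 7.51 |
| astringency | quickprop, lr 0.9, 9(sigmoid)-11(gaussian), sin out | 0.764  | 52.1   | 15.14 |

Read: the networks recover sweetness and sourness almost perfectly from
the colour fingerprint (R² > 0.95 on the 10 held-out samples) while
astringency — driven by tannin, a minor contributor to the colour signal —
is predicted only approximately, with an error around 15% of its range.
The three leading principal components of the 24-feature matrix explain
87.3% of its variance, and the PC1–PC2 score plot separates the sweet
and dry wine groups.

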