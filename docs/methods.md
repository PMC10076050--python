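# Methods

This note documents the models and procedures implemented in `phycospec`,
the defaults and why they were chosen, and what the synthetic experiments do
and do not demonstrate.

## The measurement problem

A thallus's Vis–NIR reflectance spectrum carries pigment information in the
visible (absorption wells of PE at ~500/570 nm, PC at ~620 nm, APC at
~650 nm, Chla at ~440/660 nm), rises sharply across the red edge (~700 nm),
stays high over the NIR plateau, and dips near 970 nm from the O–H
stretching overtone of tissue water. Calibration means regressing reference
pigment contents (mg/g fresh weight, from extraction spectrophotometry) on
such spectra, so that new thalli — or individual pixels — can be quantified
without destruction.

## Synthetic data generator

The generator exists because calibration methods can only be validated
against known ground truth. It produces spectra from a single-layer
Beer–Lambert model:

    R(λ) = plateau(λ) · exp(−Σ_p c_p·k_p(λ) − k_w(λ))

* `k_p(λ)`: sum of Gaussian kernels per pigment, parametrized by center
  (nm), width (SD, nm) and strength (specific absorption per mg/g).
  Defaults: PE {500, 570}, PC {620}, APC {650}, Chla {440, 660} nm, all
  widths 12 nm. Strengths (PE 0.08 per band, PC 0.15, APC 0.08,
  Chla 0.30/0.25) are set so mid-range concentrations land visible
  reflectance in roughly 0.3–0.7. APC is deliberately weak and overlaps the
  Chla 660 nm band: it is the hardest pigment to calibrate, and the grid
  experiment is expected to rank it below PE.
* `plateau(λ)`: logistic sigmoid from a visible baseline of 0.55 to an NIR
  plateau of 0.85, centered at 705 nm with 15 nm width — the simplest shape
  reproducing the red-edge jump without extra parameters.
* `k_w(λ)`: one Gaussian at 970 nm (width 25 nm, strength 0.12).

Measurement noise is applied per spectrum as `(1 + m)·R + b + ε` with
`m ~ N(0, 0.03)` (illumination/gain scatter), `b ~ N(0, 0.01)` (baseline
offset), `ε ~ N(0, 0.005)` iid per band (sensor noise). These defaults are
the "moderate noise" study condition used by the acceptance experiment; SNV
and MSC exist precisely to remove the `(m, b)` scatter component.

Reference concentrations are drawn uniformly over the laboratory calibration
ranges (PE 1.84–13.45, PC 0.96–5.27, APC 0.43–2.35, Chla 0.29–2.23 mg/g);
a narrower "field-collected" set of ranges is available for external
validation scenarios. Uniform sampling matches the documented calibration
span; contents outside the span are known to extrapolate poorly.

Cubes place an axis-aligned elongated ellipse (the thallus) in the frame,
with per-pixel concentrations interpolating linearly from the holdfast end
to `gradient_factor ×` the base panel at the tip, emulating the observed
holdfast-to-tip concentration increase. The background is a flat bright
reference surface (reflectance 0.90).

The wet-chemistry emulator treats the pigment equations as opaque linear
maps: a 3×3 matrix from absorbances (A498, A614, A651) to (PE, PC, APC)
extract concentrations and a 2-vector from (A646, A663) to Chla, shipped in
`data/wet_chem.yaml` (transcribed from the standard red-algal
phycobiliprotein and 80 %-acetone chlorophyll equations, rescaled to mg/mL).
Tissue content is `extract concentration × extract volume / fresh weight`
(8 mL pooled buffer, 6 mL acetone, 0.5 g nominal subsample). Simulating
absorbances from a panel requires inverting the Chla map, which is
underdetermined (two absorbances, one concentration); a fixed A646/A663
extract shape ratio of 0.35 closes it. The inversion applied to noisy
absorbances can yield negative contents; values above −1e−6 mg/g are clamped
to zero and anything lower is passed through flagged rather than hidden.

**What the generator does not emulate:** multi-layer or scattering optics
(no radiative transfer), fluorescence, instrument point-spread and smile,
wavelength miscalibration, spatially correlated noise, and biological
covariance between pigments (concentrations are drawn independently).
Passing the recovery tests therefore shows the pipeline is correct and
well-conditioned under the stated optical model — not that real thalli will
reach the same accuracy.

## Cube I/O and ROI

The ENVI dialect is the minimal Specim-style subset: mandatory header fields
samples/lines/bands/data type/interleave/byte order/wavelength; data types
uint16 (code 12) and float32 (code 4); interleaves BSQ/BIL/BIP. Unknown
fields are ignored with a logged warning; wavelengths are serialized with
full round-trip precision. In memory the band axis is always last,
row-major, 0-based.

Reflectance calibration divides by the white–dark gap and multiplies by the
reference-panel reflectivity (0.99 for a 99 % panel). Calibrated values are
clipped to [0, 1.5] — above 1.0 to preserve specular outliers for highlight
detection while bounding numerics — and the clip count is reported.

Automatic ROI masking uses a red-edge contrast rule: a pixel is foreground
if its mean NIR (≥720 nm) reflectance exceeds 0.15 and exceeds 1.3× its mean
visible (≤680 nm) reflectance; photosynthetic tissue is dark in the visible
and bright in the NIR, while flat backgrounds are not. Shadow/highlight
pixels are then trimmed at the (0.02, 0.98) brightness quantiles of the
foreground, emulating the manual exclusion practice; quantiles (0, 1)
disable the trim. Manual mask files are supported for full fidelity.

## Preprocessing

Five preset pipelines: `sg_standardize`, `sg_snv`, `sg_d1`, `sg_d2`, `msc`.

* Savitzky–Golay uses window 5, polynomial order 2; derivative presets reuse
  the same window/order with derivative order 1 or 2, and derivatives are
  scaled per nm (grid spacing) so outputs are grid-independent. Edge bands
  are handled by polynomial extrapolation of the terminal windows
  (`mode="interp"`), keeping all 204 features for every preset.
* Standardization is per-band z-scoring across samples (SNV already covers
  per-spectrum scaling); statistics are fit on the training split only and
  reused everywhere else, avoiding information leakage. Sample standard
  deviations use the n−1 denominator.
* SNV centers and scales each spectrum to unit SD; MSC regresses each
  spectrum on the training-mean reference and removes the fitted
  offset/slope. Degenerate inputs (zero-variance band, constant spectrum,
  |slope| < 1e−8) raise typed errors naming the offending bands/rows.

A caveat that matters for *noiseless* synthetic data: bands where no pigment
absorbs are then constant across samples, so per-band standardization is
degenerate there by construction; exact-recovery tests use the per-spectrum
presets instead.

## Calibration models

**PLSR** is PLS1 by NIPALS: mean-centered X and y, successive weight
vectors `w ∝ X_rᵀ y_r` (covariance maximization), X deflation per component,
regression vector `W(PᵀW)⁻¹q`. NIPALS was chosen over SIMPLS because it is
the textbook covariance-maximization form and easy to verify against an
independently coded oracle. Components stop early if the residual is
numerically exhausted (weight norm ≤ 1e−13 relative). The component count
n_LV (candidates up to min(50, n−2, B)) is selected at the minimum
leave-one-out RMSECV, ties toward the smaller model; each LOOCV fold refits
any train-statistic preprocessing so the estimate is leakage-free. One
NIPALS run per fold supplies the whole candidate path, which is
arithmetically identical to refitting per component count.

**SVR** is ε-insensitive support vector regression with RBF kernel
`exp(−g‖u−v‖²)`, solved by libsvm (scikit-learn) in precomputed-kernel mode
on internally z-scored features and target (population SD; zero SDs replaced
by 1). Scaling is stored in the model, so a fitted model is a self-contained
set of support vectors, dual coefficients, bias and scaling state, and the
kernel is always evaluated by this package. ε defaults to 0.1 on the
unit-variance target. (C, g) are selected by seeded 5-fold CV RMSE over
powers-of-two grids C ∈ {2⁻⁵ … 2²¹}, g ∈ {2⁻¹⁸ … 2⁵}, ties toward smaller C
then smaller g. Grid search reuses the per-fold scaled distance matrix
across the grid — bit-identical to refitting each pair, as the CV-oracle
test asserts. Single fits use KKT tolerance 1e−6; grid search and the final
refit at the selected pair use the working tolerance 1e−3 with a 10⁵–10⁶
iteration cap (a capped unconverged fit raises in strict mode and is
tolerated during selection).

The train/test split is a seeded uniform random partition; the default test
fraction 17/96 reproduces the canonical 79/17 split at n = 96. The grid
experiment reuses one split for every pigment × preset × model cell so the
two model families see identical data.

## Evaluation

* RMSE = √(mean(y−ŷ)²), in mg/g.
* RPD = SD(y)/RMSE with the n−1 SD of the *evaluation split itself*
  (chemometrics convention; the whole-dataset variant is computable by
  calling `rpd` on pooled data). Perfect predictions yield an infinity flag
  rather than a numeric, keeping tables serializable.
* MAPE = mean|y−ŷ| / mean(y) × 100 %. The denominator is the mean of the
  measured values — deliberately, matching the convention this pipeline
  follows; the per-sample-denominator variant is behind a flag.
* R² = 1 − SS_res/SS_tot (Nash–Sutcliffe form), which penalizes bias and is
  stricter than squared Pearson correlation; the latter is available as an
  option.
* RPD classes: > 3.0 quantitative, 2.0–3.0 qualitative (the 3.0 boundary
  deliberately falls in the lower class, as the quantitative class is an
  exclusive "greater than"), < 2.0 insufficient. MAPE < 15 % flags high
  accuracy.

The per-pigment optimum is the cell with the highest test RPD, ties broken
by lower test MAPE.

## Prediction maps

Each masked pixel's spectrum passes through the model's stored
preprocessing — stateless steps per pixel, learned statistics reused from
training (the only self-consistent way to transfer ROI-level preprocessing
to pixels) — and the predictor. Raw predictions are kept; negatives are
counted and clipped to zero only in the display copy, so diagnostics see the
unclipped values while rendered maps match the nonnegative blue→red scale.
The axial profile projects masked pixels onto the mask's principal axis
(second-moment eigenvector, sign-fixed for determinism) and averages
predictions in 50 bins by default. Render color limits default to the
1st/99th percentiles of the masked values and are written to a JSON sidecar.

## Problem sizes and numerical choices

The acceptance experiment uses the generator's default study conditions:
n = 96 samples, 204 bands, noise (0.005, 0.03, 0.01), one seeded 79/17
split, the full 4 × 5 × 2 grid (40 fits; LOOCV to 50 latent variables for
PLSR, 27 × 24 powers-of-two CV grid for SVR) — about 40 s on one CPU.
Mapping fidelity uses a 128 × 128 noiseless factor-2 gradient cube and a
48-sample noiseless training set. Tolerances in oracle tests: S-G vs
brute-force 1e−9; NIPALS vs oracle 1e−8; PLSR = OLS 1e−6 relative; SVR vs
QP 1e−5; CV tables vs explicit refitting 1e−12 relative (exact up to BLAS
summation order).

## Known limitations

* The generator's independence of pigment concentrations understates the
  collinearity of real biological samples; real APC calibration is likely
  harder than the synthetic analog suggests.
* The ENVI dialect is deliberately minimal (no BIP offsets, no big-endian,
  two data types).
* `auto_roi` is a stand-in for manual ROI selection; its thresholds suit
  bright flat backgrounds and photosynthetic foregrounds, not arbitrary
  scenes.
* SVR grid search at extreme C relies on an iteration cap; selected optima
  are refit and in practice converge, but pathological targets can leave
  capped cells in the CV table.
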