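# Methods

This note documents the models implemented in `endospectra`, the
defaults chosen where the design was open, and what the synthetic
fixtures do and do not establish.

## Colorimetry

All spectral quantities live on a fixed grid of 380–780 nm at 1 nm
(401 samples). Tristimulus values use the reflective convention
(reference white Y = 100).

* **Transfer function.** Display RGB is decoded with the piecewise sRGB
  electro-optical transfer function (linear segment below 0.04045,
  exponent 2.4 above); a pure power law is available via the `gamma`
  argument for cameras without the sRGB toe.
* **Primaries.** Linear RGB → XYZ uses the standard IEC 61966-2-1 sRGB
  matrix unless overridden; the matrix must be invertible so the display
  path round-trips.
* **CIELAB.** f(n) = n^(1/3) for n > 0.008856, else 7.787 n + 16/116
  (≈ 0.137931); L\* = 116 f(Y/Yn) − 16, a\* = 500 [f(X/Xn) − f(Y/Yn)],
  b\* = 200 [f(Y/Yn) − f(Z/Zn)]. An all-zero reflective input would give
  L\* = −4.6·10⁻⁴ through the linear branch; it is clamped to 0, since
  reflective imagery cannot be darker than black (the unclamped value is
  available via `clamp_negative_l=False`).
* **CIEDE2000** is implemented from the published reference formula
  (Sharma, Wu & Dalal 2005 implementation notes) with kL = kC = kH = 1,
  and verified in the test suite against the standard 34-pair set and
  against an independent implementation (scikit-image) on random pairs.
* **Observer and illuminant.** The CIE 1931 2° color-matching functions
  are generated from the Wyman–Sloan–Shirley multi-lobe piecewise
  Gaussian fit (accurate to ≈ 1 % of peak), so the package carries no
  tabulated data; exact tabulations can be loaded from two/four-column
  text files. The default illuminant is a peak-normalized 6500 K
  Planckian radiator — a smooth stand-in for a broadband endoscope lamp.
  White points are always computed from the configured illuminant and
  CMFs, never hard-coded, because rendering is tied to the instrument's
  light source.

## Camera calibration

The correction maps camera XYZ to chart-target XYZ through a linear
model on a monomial expansion of (X, Y, Z)/100:

* **Term set.** Default is the full cubic basis — 20 monomials of total
  degree ≤ 3, constant first. The constant term doubles as the dark
  channel: a constant offset in linear camera RGB appears as a constant
  XYZ shift and is absorbed exactly (a separate dark-frame subtraction
  hook exists but is off by default). Degree is capped at 3 to avoid
  over-rectification.
* **Solver.** Minimum-norm least squares (`numpy.linalg.lstsq`). With
  24 patches against 20 terms the system is near-square: on *exact*
  (noiseless) chart data the unique exact-fit solution is recovered —
  in particular, the identity when no correction is needed — but noisy
  chart measurements make the fitted polynomial wiggle between patches
  and extrapolate violently outside the chart gamut. An optional ridge
  parameter (never shrinking the constant/dark term) damps this; it is
  off by default, and rank-deficient designs (e.g. a neutral-axis-only
  chart) raise an error suggesting a smaller term set. Chart RGB values
  are treated as patch means, i.e. float-precision, not quantized.
* **Standardization.** Whether the expanded variables should be z-scored
  before regression is ambiguous in general; default is no
  standardization, with a `standardize` flag (both paths tested — on
  training data they agree, as they must for an invertible reparametrization).
* **Diagnostics.** Per-patch XYZ RMSE and mean ΔE₀₀ before/after
  correction are stored with the model; corrected tristimulus values are
  clamped at 0 (physical nonnegativity) with clamp counts logged.

## Spectral reconstruction

The chart's 24 reference spectra form a 401×24 matrix. Spectra are
mean-centered and decomposed by SVD; the model keeps the smallest k
whose cumulative explained variance reaches the threshold (default
0.99). A multiple regression maps expanded corrected XYZ of the patches
to their k principal scores; prediction is mean + basisᵀ·scores, clipped
to [0, 1.05] (slight regression overshoot above 1 is tolerated; clips
are logged).

Two design points deserve explanation:

* **Scores, not spectra.** The regression predicts k ≤ 23 principal
  scores rather than 401 spectral samples directly — dimensionally far
  safer with 24 training samples. Direct-spectrum regression can be
  emulated by setting the variance threshold to 1.0.
* **Affine score regression by default.** The score regression uses the
  expansion (1, X, Y, Z) by default rather than the full cubic set used
  for calibration. Measured across seeded closed-loop runs, a cubic
  score map fitted on 24 patches reproduces the chart exactly but
  extrapolates catastrophically on scene colors outside the chart gamut
  (phantom spectral RMSE up to ≈ 0.5); the affine map generalizes
  (≤ 0.02). The cubic expansion remains available through the
  `score_terms` argument.

Whole-frame conversion reconstructs each *distinct* RGB triple once and
scatters the spectra back to pixel positions — identical output to the
per-pixel path (asserted in tests), much faster on 8-bit frames. A model
is bound to the calibration record it was fitted with; nothing is shared
across endoscopes.

## Band operations

* **Band images** are Gaussian-weighted spectral averages (weights
  normalized to sum 1, so a flat cube maps to its own level and the
  operation is linear in the cube). Default narrow-band centers 415 and
  540 nm with 30 nm FWHM — typical of narrow-band interference filters.
* **False-color mixing.** Display red is fed by the 540 nm image, green
  and blue by the 415 nm image, then sRGB-encoded. A spectrally flat
  scene renders neutral by construction; hemoglobin-like absorbers
  darken both bands, reproducing the brown (superficial) / cyan (deep)
  vessel convention qualitatively. The 3×2 mixing matrix is
  configurable; no vendor tone curves or edge enhancement are modeled.
* **Band ranking** scores wavelength j as Σᵢ varᵢ · basis²ᵢⱼ — each
  band's share of the retained spectral variance — and picks bands
  greedily from the top score down with a minimum 10 nm separation
  (disable by setting the separation to 0). This is standard PCA loading
  analysis: deterministic and fully reproducible.

## Evaluation machinery

* **Confusion metrics.** precision = TP/column sum (defined as 0 with a
  warning when the class is never predicted), recall = TP/row sum, F1 =
  harmonic mean, accuracy = trace/total. `weighted_accuracy_from_recalls`
  implements the exact identity accuracy = Σ n₍c₎·recall₍c₎/N, which
  lets a printed report table (recalls + class sizes) be audited without
  its confusion matrix. Printed percentages round half away from zero.
* **Two-factor ANOVA without replication.** Classical decomposition
  SS_total = SS_rows + SS_cols + SS_residual with df (r−1), (c−1),
  (r−1)(c−1); each factor's F uses the residual mean square, p-values
  from the upper F tail; no multiple-testing correction. Complete tables
  are required — missing cells are an error, not imputed. Per-column
  mean ± sd is reported (the "modality mean" summary).
* **Image quality.** SSIM (11×11 Gaussian window, σ = 1.5, K1 = 0.01,
  K2 = 0.03, via scikit-image) and PSNR = 10·log₁₀(peak²/MSE) with an
  infinite flag at MSE = 0; spectral RMSE over the 401-sample grid.

## Reference classifier

A single-layer softmax model Z = WX + b over flattened grayscale
features (Rec.601 luminance, bilinear resize; 256×256 → 65,536 features
at full scale), cross-entropy loss, and moment-based updates

    m_t = β₁ m_{t−1} + (1−β₁) g,   v_t = β₂ v_{t−1} + (1−β₂) g²,
    θ_t = θ_{t−1} − η m_t / (√v_t + ε)

*without* bias correction by default (switchable); β₁ = β₂ = 0
degenerates to sign-normalized SGD. Defaults: 300 epochs, batch 64,
η = 10⁻³, β₁ = 0.9, β₂ = 0.999, ε = 10⁻⁸, zero initialization, seeded
mini-batch shuffling (bit-identical reruns). Probabilities are computed
with max-subtraction; cross-entropy floors probabilities at 10⁻¹².
Argmax ties break toward the lowest class index. This is a desk-scale
demonstrator, not a competitive image classifier.

## Synthetic fixtures and what they show

The synthetic world is deliberately low-dimensional. Per world seed,
all reflectances are drawn from a 3-component family: a broad smooth
baseline (2–4 Gaussian bumps, 60–150 nm widths, plus a flat floor) and
two ≈ 30 nm Gaussian shapes centered at 415 and 540 nm. Chart patches
take random coefficients over this family (each patch spectrum is a
band-limited sum of ≤ 6 Gaussian bumps in [0, 1]); phantom tissue takes
a slowly varying brightness field, per-class tints along the two
absorption shapes, and vessel masks (random dilated walks, 2–6 px) whose
coefficients dip at both absorption centers with seed-jittered strength.
Eight class presets (normal, staining, cancer, varicose, esophageal
junction, inflammation, duodenum, stomach) differ in brightness range,
tint, vessel density and absorber strength; the default dataset layout
emits 2400 frames split 1800/400/200 with cancer and varicose twice the
size of other classes.

The synthetic camera is colorimetric by default (sensitivities equal to
the CMFs), with optional dark offset, Gaussian noise in the linear
domain (default 0 for oracle tests, 0.01 for robustness tests), an
optional cubic XYZ distortion, and optional 8-bit quantization. Chart
measurements are float (patch means); phantom frames are 8-bit PNGs.

**Why the shared family matters.** Recovering 401 spectral samples from
3 color coordinates is only well-posed when scene reflectances lie on a
low-dimensional manifold spanned by the calibration spectra. With the
shared family, the XYZ→spectrum map is affine and exactly learnable, and
the closed loop (chart → camera → calibration → reconstruction →
phantom conversion) recovers ground-truth cubes to ≤ 0.02 RMS
reflectance across seeds, 8-bit frame quantization included. With
independently random spectra the same criterion is unattainable for
*any* XYZ-based method — two metamers demand different spectra from the
same input. Passing tests therefore certify the pipeline's correctness
on its own model assumptions; they do not certify spectral accuracy on
real tissue, whose reflectance dimensionality, specular highlights,
inter-patient variability and illumination geometry the phantoms do not
emulate.

## Numerical choices and degenerate inputs

* XYZ is divided by 100 before monomial expansion so cubic terms stay
  O(1); the expansion rejects degree > 3 and empty term lists.
* An all-identical chart yields k = 0 and a constant (mean-spectrum)
  model; a variance threshold outside (0, 1] is an error; a 0-pixel or
  non-3-channel frame is an error; band centers outside the grid and
  non-positive FWHM are errors.
* PCA uses SVD of the centered 401×24 matrix; component count is capped
  at the matrix rank; basis orthonormality is asserted to 1e-8 in tests.
* The ENVI-style cube container stores a text header (samples, lines,
  bands, wavelengths) plus little-endian float32, band-interleaved by
  pixel, row-major, origin top-left, band axis last; readers validate
  the 401-band grid and report malformed header lines with line numbers.
* All generators and the pipeline runner derive their randomness from a
  single seed through named SHA-256 substreams; reruns are bit-identical
  (checksummed in the run summary).

## Problem sizes

Test and demonstration runs use 24-patch charts, 32×32 to 64×64 phantom
frames, 10–20 seed sweeps, and 2-D blob fixtures for the classifier —
sizes at which every oracle comparison runs in seconds while exercising
identical code paths to full-scale frames (the conversion is per-pixel
and memoized, so frame size changes cost, not behavior).

## Known limitations

* Chromatic adaptation between illuminants, wide-gamut encodings,
  vignetting/lens-shading and spatially varying illumination are out of
  scope.
* The unregularized cubic correction is sensitive to chart noise (use
  the ridge option on noisy charts); reconstruction accuracy degrades
  gracefully but measurably with camera noise.
* Band selection is validated by construction on synthetic ensembles;
  there is no external reference list of "correct" bands to compare
  against.
* The reference classifier's fixed 300-epoch schedule has no early
  stopping; it is meant for pipeline demonstrations and gradient-level
  verification, not accuracy claims.
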