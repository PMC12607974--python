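# endospectra

Calibrated RGB→hyperspectral conversion for endoscopic imaging, with
simulated narrow-band rendering and the evaluation machinery that goes
with it.

## The problem

White-light endoscopy (WLI) records ordinary RGB frames: three broad
spectral integrals per pixel. Narrow-band imaging (NBI) hardware instead
illuminates tissue at 415 nm and 540 nm — the Soret and β absorption
peaks of hemoglobin — so mucosal capillaries absorb strongly and stand
out, which helps early-lesion detection. `endospectra` reconstructs, per
pixel, a full 401-sample reflectance spectrum *R(λ)* on 380–780 nm at
1 nm from an ordinary RGB frame, so that narrow-band views and arbitrary
band images can be synthesized computationally, without narrow-band
optics.

The reconstruction chain, fitted once per endoscope against a 24-patch
Macbeth-style reference chart:

1. **Linearization** — sRGB decode, then the primaries matrix gives
   camera tristimulus values *XYZ*<sub>camera</sub>.
2. **Polynomial camera correction** — a least-squares map
   *XYZ*<sub>correct</sub> = *C* · *V*(*XYZ*<sub>camera</sub>), where
   *V* stacks all monomials of total degree ≤ 3 (20 terms; the constant
   doubles as the dark-offset channel). Fit quality is scored per patch
   by XYZ RMSE and CIEDE2000 (ΔE₀₀) before/after.
3. **Spectral reconstruction** — the chart's reference spectra form a
   401×24 matrix; PCA keeps the smallest number *k* of components whose
   cumulative explained variance reaches 99 %, and a multiple regression
   maps (an expansion of) corrected XYZ to the principal scores:
   *R̂(λ)* = *μ(λ)* + **B**ᵀ·(**M**·*V*(*XYZ*<sub>correct</sub>)).
4. **Band operations** — Gaussian-window band images (default FWHM
   30 nm) at 415/540 nm are mixed into a false-color NBI-style
   rendering; an eigenvector loading score ranks the most informative
   wavelengths.

Alongside the imaging core the package ships the evaluation arithmetic
used to compare imaging modalities: confusion-matrix metrics (per-class
precision/recall/F1, accuracy, macro/weighted aggregation, the audit
identity accuracy = Σ *n₍c₎*·recall₍c₎ / *N*), a two-factor ANOVA
without replication, SSIM/PSNR/spectral-RMSE scores, and a reference
multinomial logistic-regression classifier with Adam-style moment
updates. Seeded synthetic fixtures (camera, chart, vascular tissue
phantoms, a class-balanced 2400-frame dataset layout) make everything
runnable end to end with no acquisition hardware.

## Worked example

```python
import numpy as np
import endospectra as es

# a synthetic endoscope camera with uncorrected dark current
cam = es.SyntheticCamera(dark_offset=0.01)
spectra = es.make_chart(1)                      # 24 reference spectra, 401x24
chart = es.build_chart(spectra, cam)            # imaged chart record
measured = es.rgb_to_camera_xyz(chart.rgb_measured)

calib = es.fit_correction(chart, measured)      # degree-3 polynomial fit
d = calib.diagnostics
print(f"mean XYZ RMSE: {d['mean_rmse_pre']:.3f} -> {d['mean_rmse_post']:.3e}")
print(f"mean dE00:     {d['mean_de00_pre']:.3f} -> {d['mean_de00_post']:.3e}")

model = es.fit_reconstruction(chart, calib, measured)
print(f"components: {model.n_components}, "
      f"variance retained: {100 * model.variance_retained:.2f}%")

scene = es.make_phantom(1001, size=(48, 48), label="varicose",
                        cam=cam, world_seed=1)  # tissue phantom + true cube
cube = es.convert_image(model, calib, scene.frame)
print(f"phantom spectral RMSE: "
      f"{np.sqrt(np.mean((cube.data - scene.cube.data) ** 2)):.4f}")

nbi = es.simulate_nbi(cube)                     # false-color narrow-band view
lum = nbi.mean(axis=2)
print(f"vessel/background luminance: "
      f"{lum[scene.vessel_mask].mean() / lum[~scene.vessel_mask].mean():.3f}")
```

Output:

```
mean XYZ RMSE: 1.015 -> 6.318e-14
mean dE00:     0.753 -> 1.800e-13
components: 3, variance retained: 100.00%
phantom spectral RMSE: 0.0017
vessel/background luminance: 0.730
```

The dark offset is a constant shift in linear RGB, which lies inside the
cubic correction family, so calibration removes it to machine precision.
Three principal components capture the phantom world's spectral
variability; the reconstructed cube matches the ground-truth cube to
0.002 RMS reflectance, and vessels come out 27 % darker than background
in the simulated narrow-band view — the brown/cyan vessel contrast that
narrow-band hardware produces optically.

## Command line

Every step is also a subcommand of the `endospectra` CLI:
`simulate`, `calibrate`, `convert`, `nbi`, `bands`, `quality`,
`evaluate`, `anova`, `train-ref`, and `run` (full pipeline from a
YAML/JSON config, writing a run directory with per-stage checksums).

```sh
endospectra simulate --what chart --seed 1 --out demo/
endospectra calibrate --chart-patches demo/chart_patches.csv \
    --chart-spectra demo/chart_spectra.csv --out demo/calib.json
```

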