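# ltem-restore

Restoration toolkit for liquid-phase transmission electron microscopy
(LTEM) micrographs. Micrographs of soft, organic specimens imaged in
liquid cells are doubly corrupted: heavy mixed noise (shot, readout,
impulse outliers) from low-dose acquisition, and a *spatially varying*
blur from the liquid layer, which is thickest where the pressure
difference bows the silicon-nitride windows — usually the centre of the
field of view. Conventional TEM restoration handles neither well.

`ltem-restore` implements a three-stage pipeline that recovers a sharp,
low-noise image from a single recorded frame, modelled as
`I_N = I_O ⊛ B + N`:

1. **Preprocess** — a 3×3 median filter removes salt-and-pepper outliers
   (`I_Nd`), and per-patch mean subtraction zero-centres the illumination.
2. **Progressive dual-domain denoising** — an iterative denoiser (default
   30 iterations) that re-estimates the working noise level each pass and
   applies a per-pixel filter combining a bilateral (spatial-domain)
   estimate with Fourier-domain shrinkage of the windowed residual,
   producing the blurred low-noise image `I_B`.
3. **Patch-local blind deconvolution** — the image is tiled into
   overlapping 128-px patches at stride 8; for each patch a small blur
   kernel is estimated from the pair (`I_B`, `I_Nd`) by non-negative
   Tikhonov least squares, the *residual* is deconvolved with a few
   Richardson–Lucy passes (which suppresses ringing compared with
   deconvolving the image itself), and the restored patches are blended
   with a raised-cosine window. The per-patch kernel field directly maps
   the liquid-thickness (bulging) profile.

Because no real liquid-cell micrograph comes with ground truth, the
package bundles a synthetic scene generator (vesicles = membrane annuli,
micelles = filled discs, ferritin-like dots; centre-heavy Gaussian blur
fields; Poisson + Gaussian + salt-and-pepper noise) and an edge-spread
analysis (vertically averaged ROI profiles, 10–90% rise distance) so every
stage is quantitatively testable. See `docs/methods.md` for the models,
defaults and their rationale.

## Worked example

Simulate a degraded scene, restore it, and score an edge:

```bash
cat > scene.yaml <<'EOF'
scene:
  image_size: [256, 256]
  background: 0.75
  particles:
    - {kind: vesicle, centre: [70, 80], radius: 34, contrast: -0.35, membrane_thickness: 4}
    - {kind: micelle, centre: [170, 185], radius: 28, contrast: -0.30}
    - {kind: dot, centre: [40, 160], radius: 5, contrast: -0.40}
blur:  {model: bulging, sigma_min: 0.5, sigma_max: 3.0, kernel_support: 25}
noise: {gaussian_sigma: 0.08, poisson_scale: 200, sp_fraction: 0.01, seed: 2}
EOF
ltem-restore simulate --scene scene.yaml --out sim/
ltem-restore run --input sim/degraded.tif --output-dir restored/ \
    --illum-patch 256 --save-intermediates
ltem-restore edge --input restored/degraded_restored.tif --roi 164,135,12,44
```

`run` prints per-stage wall times and writes `degraded_restored.tif` plus
a kernel-field sidecar (`degraded_kernels.npz`). The `edge` command writes
the averaged, interpolated profile across the micelle's left edge as CSV
and reports `10-90% rise distance: 4.10 px`; the same ROI on the raw
`sim/degraded.tif` reports `31.10 px` — noise and blur inflate the
measured edge width, restoration shrinks it.

The same machinery is available as a library:

```python
from ltem_restore import synthetic, evaluation

report = evaluation.denoising_comparison(seed=1, size=256)
print(round(report["psnr_raw"], 1), round(report["psnr_pid_30"], 1))
# 19.7 29.7   (dB vs the known clean phantom)
```

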