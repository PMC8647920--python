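# Methods

This note documents the models and numerical choices behind `ltem-restore`:
a three-stage pipeline that recovers a sharp, low-noise image from a single
liquid-phase transmission electron microscopy (LTEM) micrograph, together
with the synthetic scenes used to validate it quantitatively.

## Forward model

A recorded micrograph is modelled as

```
I_N = I_O ⊛ B + N
```

where `I_O` is the unknown clean image, `B` a blur kernel and `N` additive
noise. In a liquid cell `B` is *spatially varying*: differential pressure
bows the silicon-nitride windows outward, so the liquid layer — and with it
the blur — is thickest near the centre of the field of view. `N` mixes
beam/shot noise, detector readout noise and isolated extreme-valued
("salt-and-pepper") pixels.

All intensities are normalized to `[0, 1]` on load (`normalize_intensity`);
every parameter below (noise sigmas, range scales) is defined on that
scale. Constant images normalize to all-0.5 by convention so degenerate
inputs still flow through the pipeline. Pixel coordinates are 0-based
`(row, col)`, row 0 at top.

## Stage 1 — preprocessing

A `3×3` median filter removes impulse pixels (the smallest window that
deletes isolated outliers while preserving 2-pixel features; configurable).
The image is then tiled into non-overlapping blocks (default 64 px) and
each block's mean is subtracted, flattening slow illumination bias and
centring the data at zero. Ragged edge blocks are centred as their own
smaller blocks so the shape is preserved. Border handling is reflect
padding throughout the package.

The 64 px default assumes illumination varies slowly relative to specimen
features — true for multi-kilopixel micrographs. On small synthetic scenes
(128–256 px) whose particles span a block, zero-centring a block would
erase real structure, so the evaluation fixtures set the block size to the
image size (one global block). The median-filtered image `I_Nd` is kept: it
later serves as the sharp/noisy input to deblurring.

## Stage 2 — progressive dual-domain denoising

The denoiser iterates a per-pixel dual-domain filtering step. For each
pixel, over a `(2r+1)²` window (default radius `r = 15`):

1. a bilateral weight `k = exp(-(g - g_c)² / (2 γ_r σ²)) · G_spatial`
   combines a range kernel on guide-image differences with a spatial
   Gaussian (`σ_s = 7` px);
2. the spatial estimate `s` is the bilateral-weighted mean of the window;
3. the bilateral-windowed residual `k·(y - s)` is Fourier-transformed and
   each coefficient shrunk by `exp(-γ_f σ² Σk / |G|²)` (clamped to [0,1];
   `|G|²` is the guide's windowed-residual spectrum), and the inverse
   transform at the centre pixel is added back to `s`.

With no shrinkage the step is the identity; with full shrinkage it is a
bilateral filter. `σ = 0` is an exact fixed point.

Across iterations the working noise level is annealed geometrically
(`σ_{i+1} = a·σ_i`, default `a = 0.93`) starting from a robust estimate
(median absolute deviation of the finest diagonal wavelet band / 0.6745,
db2, symmetric extension). Each pass filters the *running output*, using it
as its own guide. The per-pass shrinkage is deliberately gentle
(`γ_f = 0.03`): noise is removed gradually over ~30 passes, in step with
the annealed sigma, rather than in one aggressive pass — this is what keeps
the scheme artifact-free and makes the iteration count the dominant quality
parameter. With these defaults quality improves markedly up to ~30
iterations and saturates beyond, so 30 is the default.

The window transform is computed per pixel but vectorized over row batches;
it is exactly the per-pixel definition (the test suite checks equality with
a literal per-pixel implementation to 1e-12).

Defaults were chosen on the standard synthetic fixture (below) before being
frozen; they are exposed in `DenoiseConfig` as tuning knobs.

## Stage 3 — LED patch-local blind deconvolution

Deblurring uses two images: the denoiser output `I_B` (blurred, low noise)
and the median-filtered image `I_Nd` (sharp, noisy). Because the denoiser
works on the zero-centred image, `I_B` is affinely re-aligned to `I_Nd`'s
mean/std before estimation.

The image is tiled into overlapping patches (default 128 px, stride 8 —
the standard operating point; the last patch in each row/column is clamped
to the border). Per patch:

**Kernel estimation.** Solve

```
min_k ‖b − s ⊛ k‖² + λ‖k − δ‖²,   λ = reg_weight · ‖A‖²
```

subject to `k ≥ 0`, on an odd square support (default 25×25), where the
data fit runs over the patch interior ("valid" region) so no boundary
assumption enters the operator. The ridge is centred on the delta kernel —
the neutral element of deconvolution — so an uninformative (flat) patch
yields "do nothing" rather than a spurious spread kernel. The solver is
accelerated projected gradient (FISTA, default 300 iterations, delta
start, non-negativity projection every step) with all convolutions done
through one cached FFT of the patch; the patch mean is removed first (a
unit-mass kernel passes DC through unchanged), which conditions the
problem. Keeping the projection inside the iteration matters: when the
blur varies within a patch no single kernel fits the data exactly, and the
unconstrained least-squares solution turns unphysical, while the projected
iterates stay a meaningful compromise kernel. The result is renormalized
to unit mass. Everything is deterministic. Constant patches raise a
degenerate-input error (`led_deblur` substitutes a delta kernel).

`reg_weight` defaults to 1e-5 — small enough that noiseless recovery is
essentially exact, large enough to keep the normal equations well posed.
Recovery error decreases monotonically as the weight shrinks (tested).

**Residual deconvolution.** Instead of deconvolving the image (which rings
at discontinuities), deconvolve the residual `Δ = b − s ⊛ k`: lift it by a
fixed offset 1.0 so it is positive, run multiplicative Richardson–Lucy
updates (default 20) against the kernel, subtract the offset and add the
result to the sharp patch. With a delta kernel this returns `b` exactly.
Because `Δ` is small and nearly flat near edges, the ringing acts on the
offset plateau rather than on image structure; the tests verify lower MSE
than plain RL at equal iterations.

**Recombination.** Overlapping restored patches are averaged per pixel
with a separable raised-cosine window (small positive floor, so weight
sums are strictly positive even at borders). The recombination rule is
this package's choice; a uniform window is available for comparison.

`apply_foreign_kernels` replays the patch loop with a supplied kernel
field (estimation skipped) to support the artifact-control experiment:
kernels estimated on one scene applied to another should *distort* the
image, not conjure structure. Its optional `sharp=` argument lets callers
replay a paired run exactly; by default the input image serves both roles.

### Why the sharp input's noise matters

The estimated kernel is a regularized Wiener-like quotient of the
cross-spectrum (sharp, blurred) over the sharp image's power spectrum.
Broadband noise in the sharp/noisy input acts as the wideband reference
against which the blurred image's spectral roll-off is measured; a
noise-free but equally blurred "sharp" input would yield a near-delta
kernel and no deblurring. This is why the pipeline deliberately pairs the
*median-filtered* image (noise retained, impulses removed) with the
denoised one.

## Synthetic scenes

`synthetic` renders phantoms with known ground truth: membrane-bound
vesicles (annuli in projection; the lumen stays at background), solid
micelles (filled discs) and small ferritin-like dots, anti-aliased by 4×
supersampling of the indicator function. Blur fields are integrated
(pixel-binned) Gaussians per patch; the `bulging` model interpolates the
width from `sigma_min` at the image corners to `sigma_max` at the centre
with a cosine-smooth radial ramp (the real bulging profile is not known
quantitatively; the law is configuration). Degradation applies, in order:
spatially varying convolution (per-patch kernels with a full-image halo,
blended with the same raised-cosine rule — a uniform field therefore
equals one global convolution to machine precision), Poisson shot noise at
`poisson_scale` expected counts per unit intensity, additive Gaussian
readout noise, and salt-and-pepper replacement of a fixed fraction of
pixels by the clean image's global min/max (half each). All draws come
from one seeded generator.

What the generator does *not* emulate: electron-optical contrast transfer,
multislice scattering, dose-rate dynamics, drift, or camera-specific noise
correlations. Passing tests therefore demonstrate the pipeline's behaviour
under the stated degradation model, not detector-accurate physics.

### Standard study conditions

* **Mixed-noise fixture** (denoiser comparison): vesicle/micelle/dot scene,
  background 0.75, particle contrasts −0.30…−0.40, shot noise at 200
  counts per unit intensity, readout sigma 0.08, 1% impulse pixels, no
  blur — blur removal is the deblur stage's job and would cap every
  denoiser's PSNR identically.
* **Bulging-blur fixture** (spatial-variation detection): a field of ~120
  ferritin-like dots (so every 128-px patch carries texture), blur sigma
  0.5 → 3.0 px corner-to-centre, sharp reference = clean phantom + sigma
  0.01 Gaussian noise.
* **Step-edge fixture** (sharpening): a high-contrast step edge (0.2/0.9)
  with ferritin-like dots kept outside an exclusion band around the
  measurement ROI (they give the kernel estimator 2-D texture without
  ringing into the measurement). Two acquisitions are simulated — the
  dual-image setting the blurred/sharp-pair method is designed for: a
  blurred low-dose frame (uniform blur sigma 2 px, Gaussian sigma 0.06,
  shot noise at 2000 counts, 2% impulses) that is median-filtered, centred
  and denoised into `I_B`, and a sharp lightly-noisy reference frame
  (Gaussian 0.02, 1% impulses) whose median-filtered version serves as
  `I_Nd`. An
  edge-preserving denoiser leaves essentially nothing for the
  single-acquisition pair to identify at a clean synthetic edge (the
  denoised output retains the same blurred spectrum as the median image
  above the noise floor, so the estimated kernel degenerates to a delta);
  with real low-dose micrographs the noise floor sits far above the
  blurred-signal tail, which is why the single-image pipeline identifies a
  useful kernel there. The edge ROI is 8 rows tall so a single surviving
  impulse registers in the raw profile's measured rise; residual
  deconvolution runs 3 iterations on this single-patch fixture since more
  only amplify the reference frame's noise into plateau ripple.
* **Ringing fixture**: plain 128-px step edge (0.3/0.8), uniform blur
  sigma 2 px, comparing residual deconvolution against plain
  Richardson–Lucy at equal iterations with the true kernel.
* **Kernel-swap fixture** (artifact control): micelle-only scene restored
  with its own estimated field (bulging 0.5–2.5) vs a field estimated on
  the dotted scene under uniform sigma-3 blur; the foreign field
  over-deconvolves everywhere.

Problem sizes (256 px scenes, 128 px edge/ringing fixtures) were chosen so
the full evaluation battery completes in minutes on one CPU while every
patch grid still contains a meaningful number of patches.

## Edge-spread sharpness

A rectangular ROI across a particle edge is averaged along rows into a 1-D
profile, cubic-spline interpolated at 10× density, and scored by a 10–90%
rise distance: plateau levels are robust means of the first and last
profile deciles; after orienting the profile ascending, the rise spans
from the first sample at/above the 10% level to the last sample at/below
the 90% level. On a clean monotone edge this is the usual 10–90 crossing
width (≈ 2.563·σ for a Gaussian-blurred step, verified against the closed
form); residual noise or deconvolution ringing in the plateaus widens the
measure, matching the visual impression that such profiles are less sharp.
A profile whose plateau difference is under 3× its noise MAD raises a
no-edge error. The metric is invariant to affine intensity rescaling.

## Numerical conventions

* Double precision throughout; all stages are deterministic given inputs
  and configuration (bitwise reproducible).
* Reflect (symmetric) padding for every windowed or convolutional
  operation.
* FFT sizes are padded to fast lengths; per-patch convolution caches one
  real FFT of the sharp patch.
* Degenerate inputs: constant images normalize to 0.5, estimate to noise
  sigma 0, pass the denoiser unchanged, and yield delta kernels in the
  deblur loop.
* The salt-and-pepper extremes are the clean dynamic range's global
  min/max, matching the "very black and very white" pixels the median
  stage targets.

## Known limitations

* The kernel estimate is a regularized Wiener-style compromise, not the
  physical PSF; its widths are meaningful relatively (centre vs corner),
  which is what the spatial-variation analysis uses.
* Patch kernels assume the blur is locally constant per 128-px patch;
  strong within-patch gradients bias the estimate toward a patch-average
  kernel.
* The restored image inherits the sharp input's residual (non-impulse)
  noise by construction (`restored = sharp + deconvolved residual`); the
  pipeline trades a little noise for sharpness at the last stage.
* Single-frame only: no stacks, video, drift correction or CTF handling.
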