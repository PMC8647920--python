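"""Synthetic liquid-cell scenes with known ground truth.

Real liquid-phase micrographs never come with a noiseless reference, so
every quantitative check in this package runs on phantoms built here:
membrane-bound vesicles (annuli in projection), solid micelles (filled
discs) and small ferritin-like dots, degraded through the forward model

    observed = clean (*) blur_field + noise

with a spatially varying Gaussian blur field (maximum width at the image
centre, emulating the bulging of the silicon-nitride windows) and mixed
Poisson shot noise, additive Gaussian readout noise and salt-and-pepper
outlier pixels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import yaml
from scipy import signal
from scipy.special import erf

from .image_model import Image, ValidationError
from .led_deblur import BlurKernel, KernelField, _patch_positions, _blend_weights

__all__ = [
    "Particle",
    "SceneSpec",
    "BlurFieldSpec",
    "NoiseModel",
    "make_phantom",
    "make_kernel_field",
    "degrade",
    "psnr",
    "load_scene_config",
    "standard_scene",
    "standard_noise",
]

_SUPERSAMPLE = 4  # anti-aliasing factor for particle edges


@dataclass(frozen=True)
class Particle:
    """One simulated particle.

    kind: 'vesicle' (membrane annulus), 'micelle' (filled disc) or 'dot'
    (small filled disc, ferritin-like). ``contrast`` is added to the
    background inside the particle (negative = darker than background).
    ``membrane_thickness`` applies to vesicles only.
    """

    kind: str
    centre: tuple[float, float]
    radius: float
    contrast: float
    membrane_thickness: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("vesicle", "micelle", "dot"):
            raise ValidationError(f"unknown particle kind {self.kind!r}")
        if self.radius <= 0:
            raise ValidationError("particle radius must be positive")
        if self.kind == "vesicle" and not 0 < self.membrane_thickness < self.radius:
            raise ValidationError("vesicle needs 0 < membrane_thickness < radius")


@dataclass(frozen=True)
class SceneSpec:
    image_size: tuple[int, int]
    particles: Sequence[Particle] = field(default_factory=tuple)
    background: float = 0.7
    seed: int = 0
    jitter: float = 0.0  # optional centre jitter (px std), drawn from seed

    def __post_init__(self) -> None:
        h, w = self.image_size
        if h < 1 or w < 1:
            raise ValidationError(f"invalid image size {self.image_size}")
        for p in self.particles:
            r, c = p.centre
            if not (p.radius <= r <= h - 1 - p.radius and p.radius <= c <= w - 1 - p.radius):
                raise ValidationError(f"particle at {p.centre} r={p.radius} exceeds bounds {self.image_size}")


@dataclass(frozen=True)
class BlurFieldSpec:
    """Spatially varying Gaussian blur description.

    model 'uniform': every patch kernel has width sigma_max. model
    'bulging': width interpolates smoothly from sigma_min at the image
    corners to sigma_max at the centre.
    """

    model: str = "bulging"
    sigma_min: float = 0.5
    sigma_max: float = 3.0
    kernel_support: int = 25

    def __post_init__(self) -> None:
        if self.model not in ("uniform", "bulging"):
            raise ValidationError(f"unknown blur model {self.model!r}")
        if not 0 <= self.sigma_min <= self.sigma_max:
            raise ValidationError("need 0 <= sigma_min <= sigma_max")
        if self.kernel_support < 1 or self.kernel_support % 2 == 0:
            raise ValidationError("kernel_support must be odd and >= 1")


@dataclass(frozen=True)
class NoiseModel:
    """Mixed noise: Poisson shot noise at ``poisson_scale`` expected counts
    per unit intensity (0 disables), additive Gaussian readout noise, then
    ``sp_fraction`` of pixels replaced by salt/pepper extremes (half each)."""

    gaussian_sigma: float = 0.0
    poisson_scale: float = 0.0
    sp_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.gaussian_sigma < 0 or self.poisson_scale < 0:
            raise ValidationError("noise levels must be >= 0")
        if not 0 <= self.sp_fraction < 1:
            raise ValidationError("sp_fraction must lie in [0,1)")


def _disc_coverage(h: int, w: int, centre, r_outer: float, r_inner: float = 0.0) -> np.ndarray:
    """Supersampled coverage fraction of an annulus r_inner < d <= r_outer."""
    s = _SUPERSAMPLE
    cr, cc = centre
    lo_r = max(0, int(np.floor(cr - r_outer - 1)))
    hi_r = min(h, int(np.ceil(cr + r_outer + 2)))
    lo_c = max(0, int(np.floor(cc - r_outer - 1)))
    hi_c = min(w, int(np.ceil(cc + r_outer + 2)))
    rows = (np.arange(lo_r * s, hi_r * s) + 0.5) / s - 0.5
    cols = (np.arange(lo_c * s, hi_c * s) + 0.5) / s - 0.5
    d2 = (rows[:, None] - cr) ** 2 + (cols[None, :] - cc) ** 2
    mask = (d2 <= r_outer**2)
    if r_inner > 0:
        mask &= d2 > r_inner**2
    frac = mask.astype(np.float64).reshape(hi_r - lo_r, s, hi_c - lo_c, s).mean(axis=(1, 3))
    cov = np.zeros((h, w))
    cov[lo_r:hi_r, lo_c:hi_c] = frac
    return cov


def make_phantom(spec: SceneSpec) -> Image:
    """Render the clean scene: anti-aliased particles on a flat background.

    Deterministic given the spec; ``spec.seed`` is used only for optional
    centre jitter when ``spec.jitter > 0``.
    """
    h, w = spec.image_size
    arr = np.full((h, w), spec.background, dtype=np.float64)
    rng = np.random.default_rng(spec.seed)
    for p in spec.particles:
        centre = p.centre
        if spec.jitter > 0:
            centre = tuple(np.asarray(p.centre) + rng.normal(0, spec.jitter, 2))
        if p.kind == "vesicle":
            cov = _disc_coverage(h, w, centre, p.radius, p.radius - p.membrane_thickness)
        else:
            cov = _disc_coverage(h, w, centre, p.radius)
        arr += p.contrast * cov
    return Image(arr)


def _gaussian_kernel(sigma: float, support: int) -> np.ndarray:
    """Integrated (pixel-binned) Gaussian kernel; sigma == 0 gives a delta."""
    m = support // 2
    if sigma == 0.0:
        k = np.zeros((support, support))
        k[m, m] = 1.0
        return k
    x = np.arange(-m, m + 1)
    g = 0.5 * (erf((x + 0.5) / (np.sqrt(2) * sigma)) - erf((x - 0.5) / (np.sqrt(2) * sigma)))
    mass = g.sum() ** 2
    if 1.0 - mass > 0.01:
        raise ValidationError(
            f"kernel support {support} truncates {1 - mass:.1%} of a sigma={sigma} Gaussian"
        )
    k = np.outer(g, g)
    return k / k.sum()


def sigma_at(spec: BlurFieldSpec, pos: tuple[float, float], image_size: tuple[int, int]) -> float:
    """Generative blur width at a pixel position (bulging: cosine-smooth
    radial ramp, sigma_max at the image centre, sigma_min at the corners)."""
    if spec.model == "uniform":
        return spec.sigma_max
    h, w = image_size
    centre = np.array([(h - 1) / 2.0, (w - 1) / 2.0])
    d = np.linalg.norm(np.asarray(pos, dtype=np.float64) - centre) / np.linalg.norm(centre)
    weight = 0.5 * (1.0 + np.cos(np.pi * min(d, 1.0)))
    return spec.sigma_min + (spec.sigma_max - spec.sigma_min) * weight


def make_kernel_field(
    spec: BlurFieldSpec,
    image_size: tuple[int, int],
    patch_size: int = 128,
    stride: int = 8,
) -> KernelField:
    """Per-patch normalized Gaussian kernels on the standard patch grid."""
    rows, cols = _patch_positions(image_size, patch_size, stride)
    kernels = np.empty((len(rows), len(cols), spec.kernel_support, spec.kernel_support))
    for i, top in enumerate(rows):
        for j, left in enumerate(cols):
            centre = (top + (patch_size - 1) / 2.0, left + (patch_size - 1) / 2.0)
            sig = sigma_at(spec, centre, image_size)
            kernels[i, j] = _gaussian_kernel(sig, spec.kernel_support)
    return KernelField(kernels=kernels, patch_size=patch_size, stride=stride, image_shape=tuple(image_size))


def _spatially_varying_convolve(arr: np.ndarray, field: KernelField) -> np.ndarray:
    """Blend per-patch *global-context* convolutions.

    Each patch is convolved together with a kernel-radius halo taken from
    the reflect-padded full image, so a uniform field reproduces one global
    convolution to machine precision.
    """
    h, w = arr.shape
    support = field.kernels.shape[-1]
    m = support // 2
    centre_mass = field.kernels[:, :, m, m]
    if np.all(centre_mass == 1.0):  # all-delta field: exact identity
        return arr.copy()
    padded = np.pad(arr, m, mode="symmetric")
    acc = np.zeros((h, w))
    wacc = np.zeros((h, w))
    weights = _blend_weights(field.patch_size, "raised_cosine")
    rows, cols = _patch_positions((h, w), field.patch_size, field.stride)
    for i, top in enumerate(rows):
        for j, left in enumerate(cols):
            region = padded[top : top + field.patch_size + 2 * m, left : left + field.patch_size + 2 * m]
            kern = field.kernels[i, j]
            if kern[m, m] == 1.0:  # exact delta: identity, bit-for-bit
                conv = region[m : m + field.patch_size, m : m + field.patch_size]
            else:
                conv = signal.fftconvolve(region, kern, mode="valid")
            acc[top : top + field.patch_size, left : left + field.patch_size] += weights * conv
            wacc[top : top + field.patch_size, left : left + field.patch_size] += weights
    return acc / wacc


def degrade(clean: Image, field: KernelField, noise: NoiseModel) -> Image:
    """Apply the forward model: spatially varying blur, then Poisson shot
    noise, Gaussian readout noise, and salt-and-pepper outliers."""
    if tuple(field.image_shape) != clean.shape:
        raise ValidationError(f"kernel field built for {field.image_shape}, image is {clean.shape}")
    arr = _spatially_varying_convolve(clean.pixels, field)
    rng = np.random.default_rng(noise.seed)
    if noise.poisson_scale > 0:
        arr = rng.poisson(np.clip(arr, 0, None) * noise.poisson_scale) / noise.poisson_scale
    if noise.gaussian_sigma > 0:
        arr = arr + rng.normal(0.0, noise.gaussian_sigma, arr.shape)
    if noise.sp_fraction > 0:
        n_bad = int(round(noise.sp_fraction * arr.size))
        idx = rng.choice(arr.size, size=n_bad, replace=False)
        lo, hi = float(clean.pixels.min()), float(clean.pixels.max())
        flat = arr.reshape(-1)
        half = n_bad // 2
        flat[idx[:half]] = lo
        flat[idx[half:]] = hi
    return Image(arr)


def psnr(a: Image, b: Image) -> float:
    """Peak signal-to-noise ratio in dB against peak 1.0; +inf if identical."""
    if a.shape != b.shape:
        raise ValidationError(f"shape mismatch: {a.shape} vs {b.shape}")
    mse = float(np.mean((a.pixels - b.pixels) ** 2))
    if mse == 0.0:
        return float("inf")
    return 10.0 * np.log10(1.0 / mse)


# ---------------------------------------------------------------------------
# standard fixtures: the study conditions used throughout the test suite

def standard_scene(size: int = 256, seed: int = 0) -> SceneSpec:
    """Mixed vesicle/micelle/dot scene scaled to ``size``.

    Geometry emulates the membrane-analysis scenes: two vesicles with thin
    dark membranes, two solid micelles and a sprinkling of ferritin-like
    dots, on a bright background (dark particles, bright-field contrast).
    """
    s = size / 256.0
    particles = [
        Particle("vesicle", (70 * s, 80 * s), 34 * s, -0.35, membrane_thickness=max(2.0, 4 * s)),
        Particle("vesicle", (170 * s, 185 * s), 28 * s, -0.35, membrane_thickness=max(2.0, 4 * s)),
        Particle("micelle", (90 * s, 190 * s), 22 * s, -0.30),
        Particle("micelle", (185 * s, 70 * s), 18 * s, -0.30),
        Particle("dot", (40 * s, 160 * s), 5 * s, -0.40),
        Particle("dot", (140 * s, 40 * s), 6 * s, -0.40),
        Particle("dot", (220 * s, 150 * s), 5 * s, -0.40),
    ]
    return SceneSpec(image_size=(size, size), particles=particles, background=0.75, seed=seed)


def dotted_scene(size: int = 256, n_dots: int = 120, seed: int = 5) -> SceneSpec:
    """Field of ferritin-like dots scattered over the whole image.

    Texture in every analysis patch makes this the fixture of choice for
    spatially-varying blur estimation: each patch sees enough edges to make
    its kernel identifiable.
    """
    rng = np.random.default_rng(seed)
    parts = []
    for _ in range(n_dots):
        r = rng.uniform(3.5, 6.5)
        cy, cx = rng.uniform(r + 2, size - 2 - r, 2)
        parts.append(Particle("dot", (cy, cx), r, -0.4))
    return SceneSpec((size, size), tuple(parts), background=0.75, seed=seed)


def make_step_edge(size: int = 128, low: float = 0.3, high: float = 0.8) -> Image:
    """Vertical step edge through the image centre (1-px linear transition)."""
    col = np.full(size, high)
    col[: size // 2] = low
    col[size // 2] = 0.5 * (low + high)
    return Image(np.tile(col, (size, 1)))


def standard_noise(seed: int = 0) -> NoiseModel:
    """Mixed-noise operating point used by the standard fixture: shot noise
    at 200 counts/unit intensity, readout sigma 0.08, 1% impulse pixels."""
    return NoiseModel(gaussian_sigma=0.08, poisson_scale=200.0, sp_fraction=0.01, seed=seed)


def load_scene_config(path) -> tuple[SceneSpec, BlurFieldSpec, NoiseModel]:
    """Read scene/blur/noise specs from a YAML mapping with keys ``scene``,
    ``blur`` and ``noise`` (all documented in the CLI help)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    scn = raw.get("scene", {})
    particles = tuple(
        Particle(
            kind=p["kind"],
            centre=tuple(p["centre"]),
            radius=float(p["radius"]),
            contrast=float(p["contrast"]),
            membrane_thickness=float(p.get("membrane_thickness", 0.0)),
        )
        for p in scn.get("particles", [])
    )
    scene = SceneSpec(
        image_size=tuple(scn.get("image_size", (256, 256))),
        particles=particles,
        background=float(scn.get("background", 0.7)),
        seed=int(scn.get("seed", 0)),
        jitter=float(scn.get("jitter", 0.0)),
    )
    blr = raw.get("blur", {})
    blur = BlurFieldSpec(
        model=blr.get("model", "bulging"),
        sigma_min=float(blr.get("sigma_min", 0.5)),
        sigma_max=float(blr.get("sigma_max", 3.0)),
        kernel_support=int(blr.get("kernel_support", 25)),
    )
    nz = raw.get("noise", {})
    noise = NoiseModel(
        gaussian_sigma=float(nz.get("gaussian_sigma", 0.0)),
        poisson_scale=float(nz.get("poisson_scale", 0.0)),
        sp_fraction=float(nz.get("sp_fraction", 0.0)),
        seed=int(nz.get("seed", 0)),
    )
    return scene, blur, noise
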