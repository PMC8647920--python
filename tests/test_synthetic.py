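import numpy as np
import pytest

from ltem_restore.image_model import Image, ValidationError
from ltem_restore.synthetic import (
    Particle,
    SceneSpec,
    BlurFieldSpec,
    NoiseModel,
    make_phantom,
    make_kernel_field,
    degrade,
    psnr,
    load_scene_config,
    standard_scene,
    make_step_edge,
    _gaussian_kernel,
)


class TestPhantom:
    def test_empty_scene_is_background(self):
        img = make_phantom(SceneSpec((32, 32), (), background=0.6))
        assert np.allclose(img.pixels, 0.6)

    def test_micelle_area_matches_disc(self):
        spec = SceneSpec((64, 64), (Particle("micelle", (32, 32), 10, -0.5),), background=1.0)
        img = make_phantom(spec)
        area = np.sum(1.0 - img.pixels) / 0.5  # coverage-weighted pixel count
        assert area == pytest.approx(np.pi * 100, rel=0.05)

    def test_vesicle_is_annulus(self):
        spec = SceneSpec(
            (64, 64), (Particle("vesicle", (32, 32), 20, -0.5, membrane_thickness=4),), background=1.0
        )
        img = make_phantom(spec)
        rr, cc = np.ogrid[:64, :64]
        d = np.hypot(rr - 32, cc - 32)
        lumen = img.pixels[d < 14]
        membrane = img.pixels[(d > 17) & (d < 19)]
        outside = img.pixels[d > 22]
        assert np.allclose(lumen, 1.0)  # hollow interior at background level
        assert np.allclose(membrane, 0.5, atol=1e-6)
        assert np.allclose(outside, 1.0)

    def test_out_of_bounds_particle_rejected(self):
        with pytest.raises(ValidationError):
            SceneSpec((64, 64), (Particle("dot", (2, 2), 5, -0.3),))

    def test_vesicle_membrane_validation(self):
        with pytest.raises(ValidationError):
            Particle("vesicle", (32, 32), 10, -0.5, membrane_thickness=12)

    def test_deterministic_and_jitter_seeded(self):
        spec = standard_scene(64, seed=3)
        assert np.array_equal(make_phantom(spec).pixels, make_phantom(spec).pixels)


class TestKernelField:
    def test_uniform_field_identical_kernels(self):
        field = make_kernel_field(BlurFieldSpec("uniform", 1.0, 1.0, 15), (128, 128), 64, 32)
        ref = field.kernels[0, 0]
        assert all(
            np.array_equal(field.kernels[i, j], ref)
            for i in range(field.grid_shape[0])
            for j in range(field.grid_shape[1])
        )

    def test_bulging_centre_wider_than_corner(self):
        field = make_kernel_field(BlurFieldSpec("bulging", 0.5, 3.0, 25), (256, 256), 64, 32)
        widths = field.widths()
        centre = widths[widths.shape[0] // 2, widths.shape[1] // 2]
        assert centre > widths[0, 0]

    def test_kernels_normalized(self):
        field = make_kernel_field(BlurFieldSpec("bulging", 0.5, 2.5, 25), (128, 128), 64, 16)
        sums = field.kernels.sum(axis=(2, 3))
        assert np.all(np.abs(sums - 1) < 1e-9)

    def test_truncating_support_rejected(self):
        with pytest.raises(ValidationError):
            make_kernel_field(BlurFieldSpec("uniform", 5.0, 5.0, 7), (64, 64), 32, 32)


class TestDegrade:
    def test_delta_field_zero_noise_identity(self, small_scene):
        _, clean = small_scene
        delta = make_kernel_field(BlurFieldSpec("uniform", 0, 0, 3), (128, 128), 64, 32)
        out = degrade(clean, delta, NoiseModel())
        assert np.array_equal(out.pixels, clean.pixels)

    def test_uniform_field_equals_global_convolution(self, small_scene):
        from scipy.signal import fftconvolve

        _, clean = small_scene
        field = make_kernel_field(BlurFieldSpec("uniform", 1.5, 1.5, 13), (128, 128), 64, 16)
        out = degrade(clean, field, NoiseModel())
        k = _gaussian_kernel(1.5, 13)
        direct = fftconvolve(np.pad(clean.pixels, 6, mode="symmetric"), k, mode="valid")
        assert np.max(np.abs(out.pixels - direct)) < 1e-6

    def test_salt_pepper_count(self):
        clean = Image(np.tile(np.linspace(0.25, 0.75, 200), (200, 1)))
        delta = make_kernel_field(BlurFieldSpec("uniform", 0, 0, 3), (200, 200), 100, 100)
        out = degrade(clean, delta, NoiseModel(sp_fraction=0.01, seed=5))
        n_impulse = np.sum(out.pixels != clean.pixels)
        assert 300 <= n_impulse <= 500

    def test_seed_reproducibility(self, small_scene):
        _, clean = small_scene
        delta = make_kernel_field(BlurFieldSpec("uniform", 0, 0, 3), (128, 128), 64, 64)
        a = degrade(clean, delta, NoiseModel(gaussian_sigma=0.1, seed=7))
        b = degrade(clean, delta, NoiseModel(gaussian_sigma=0.1, seed=7))
        c = degrade(clean, delta, NoiseModel(gaussian_sigma=0.1, seed=8))
        assert np.array_equal(a.pixels, b.pixels)
        assert not np.array_equal(a.pixels, c.pixels)

    def test_psnr_decreases_with_noise(self, small_scene):
        _, clean = small_scene
        delta = make_kernel_field(BlurFieldSpec("uniform", 0, 0, 3), (128, 128), 64, 64)
        values = [
            psnr(degrade(clean, delta, NoiseModel(gaussian_sigma=s, seed=1)), clean)
            for s in (0.02, 0.05, 0.1)
        ]
        assert values[0] > values[1] > values[2]


class TestPsnr:
    def test_identical_is_infinite(self, rng):
        img = Image(rng.random((16, 16)))
        assert psnr(img, img) == float("inf")

    def test_constant_offset(self):
        a = Image(np.zeros((10, 10)))
        b = Image(np.full((10, 10), 0.1))
        assert psnr(a, b) == pytest.approx(20.0)

    def test_matches_direct_formula(self, rng):
        a, b = Image(rng.random((16, 16))), Image(rng.random((16, 16)))
        mse = np.mean((a.pixels - b.pixels) ** 2)
        assert psnr(a, b) == pytest.approx(10 * np.log10(1 / mse))

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValidationError):
            psnr(Image(rng.random((8, 8))), Image(rng.random((9, 9))))


class TestSceneConfig:
    def test_yaml_roundtrip(self, tmp_path):
        cfg = tmp_path / "scene.yaml"
        cfg.write_text(
            """
scene:
  image_size: [64, 64]
  background: 0.8
  particles:
    - {kind: vesicle, centre: [32, 32], radius: 15, contrast: -0.3, membrane_thickness: 3}
blur: {model: uniform, sigma_min: 1.0, sigma_max: 1.0, kernel_support: 9}
noise: {gaussian_sigma: 0.05, seed: 3}
"""
        )
        scene, blur, noise = load_scene_config(cfg)
        assert scene.image_size == (64, 64)
        assert scene.particles[0].kind == "vesicle"
        assert blur.model == "uniform"
        assert noise.gaussian_sigma == 0.05


class TestStepEdge:
    def test_plateaus(self):
        img = make_step_edge(64, 0.2, 0.9)
        assert np.allclose(img.pixels[:, :31], 0.2)
        assert np.allclose(img.pixels[:, 33:], 0.9)
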