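"""Cropping, CLAHE, D-DoG masking, fusion and resizing contracts."""

import numpy as np
import pytest

import hirdnet as hn
from hirdnet.enhance import (EmptyFundusError, ImageTooSmallError,
                             gaussian_kernel_1d)

CFG = hn.EnhancementConfig()


def _constant_image(value, shape=(64, 64, 3)):
    return hn.RawFundusImage(np.full(shape, value, dtype=np.uint8), source_id="const")


# ---------------------------------------------------------------- crop


class TestCrop:
    def test_disk_bounding_box(self, disk_image):
        cropped = hn.crop_fundus(disk_image, CFG)
        assert cropped.pixels.shape == (101, 101, 3)
        # the disk touches all four edges of the crop
        assert cropped.pixels[0, 50].max() == 255
        assert cropped.pixels[50, 0].max() == 255

    def test_uniform_image_unchanged(self):
        img = _constant_image(128)
        out = hn.crop_fundus(img, CFG)
        assert np.array_equal(out.pixels, img.pixels)

    def test_all_background_raises(self):
        img = _constant_image(5)
        with pytest.raises(EmptyFundusError, match="empty fundus.*const"):
            hn.crop_fundus(img, CFG)

    def test_largest_component_wins(self):
        a = np.zeros((64, 64, 3), dtype=np.uint8)
        a[2:6, 2:6] = 200       # small blob
        a[20:50, 20:50] = 200   # large blob
        out = hn.crop_fundus(hn.RawFundusImage(a), CFG)
        assert out.pixels.shape == (30, 30, 3)

    @pytest.mark.parametrize("seed", range(4))
    def test_idempotence_on_synthetic_disks(self, seed):
        img = hn.generate_image(grade=2, seed=seed, size=96)
        raw = hn.RawFundusImage(img.pixels, source_id=f"s{seed}")
        once = hn.crop_fundus(raw, CFG)
        twice = hn.crop_fundus(once, CFG)
        assert np.array_equal(once.pixels, twice.pixels)


# ---------------------------------------------------------------- CLAHE


class TestClahe:
    def test_constant_stays_constant(self):
        out = hn.apply_clahe(_constant_image(128), CFG)
        assert out.pixels.shape == (64, 64, 3)
        assert len(np.unique(out.pixels.reshape(-1, 3), axis=0)) == 1

    @pytest.mark.parametrize("per_channel", [False, True])
    def test_shape_and_dtype_contract(self, per_channel):
        rng = np.random.default_rng(0)
        img = hn.RawFundusImage(rng.integers(0, 256, (50, 70, 3), dtype=np.uint8).astype(np.uint8))
        cfg = hn.EnhancementConfig(clahe_per_channel=per_channel)
        out = hn.apply_clahe(img, cfg)
        assert out.pixels.shape == img.pixels.shape
        assert out.pixels.dtype == np.uint8

    def test_too_small_raises(self):
        img = hn.RawFundusImage(np.full((16, 16, 3), 100, dtype=np.uint8))
        cfg = hn.EnhancementConfig(clahe_tile_grid=(20, 20))
        with pytest.raises(ImageTooSmallError):
            hn.apply_clahe(img, cfg)

    def test_single_tile_preserves_level_ordering(self):
        # two-level step pattern, one tile: histogram equalization is monotone,
        # so the dark half must stay darker than the bright half
        a = np.zeros((32, 32, 3), dtype=np.uint8)
        a[:, :16] = 60
        a[:, 16:] = 180
        cfg = hn.EnhancementConfig(clahe_tile_grid=(1, 1), clahe_per_channel=True)
        out = hn.apply_clahe(hn.RawFundusImage(a), cfg).pixels
        assert out[:, :16].mean() < out[:, 16:].mean()


# ---------------------------------------------------------------- D-DoG


def brute_force_ddog(pixels: np.ndarray, cfg: hn.EnhancementConfig) -> np.ndarray:
    """Independent O(HWk²) reference: explicit 2-D Gaussian sum with reflected
    borders, saturating subtraction, explicit 2×2 max dilation."""
    gray = pixels.astype(np.float64) @ np.array([0.299, 0.587, 0.114])
    h, w = gray.shape
    k1 = gaussian_kernel_1d(cfg.gaussian_kernel, cfg.gaussian_sigma)
    k2 = np.outer(k1, k1)
    r = cfg.gaussian_kernel // 2

    def reflect(i, n):  # scipy 'reflect' convention: (d c b a | a b c d | d c b a)
        while i < 0 or i >= n:
            i = -i - 1 if i < 0 else 2 * n - 1 - i
        return i

    blur = np.zeros_like(gray)
    for y in range(h):
        for x in range(w):
            acc = 0.0
            for dy in range(-r, r + 1):
                for dx in range(-r, r + 1):
                    acc += k2[dy + r, dx + r] * gray[reflect(y + dy, h), reflect(x + dx, w)]
            blur[y, x] = acc
    diff = np.round(np.clip(gray - blur, 0, 255)).astype(np.uint8)
    out = np.zeros_like(diff)
    for _ in range(cfg.dilation_iterations):
        for y in range(h):
            for x in range(w):
                out[y, x] = max(diff[min(yy, h - 1), min(xx, w - 1)]
                                for yy in (y, y + 1) for xx in (x, x + 1))
        diff = out.copy()
    return out


class TestDDoG:
    def test_constant_gives_zero_mask(self):
        mask = hn.compute_ddog_mask(_constant_image(90), CFG)
        assert mask.shape == (64, 64)
        assert mask.max() == 0

    def test_single_bright_pixel_dilates(self):
        a = np.zeros((16, 16, 3), dtype=np.uint8)
        a[7, 7] = 255
        mask = hn.compute_ddog_mask(hn.RawFundusImage(a, source_id="px"), CFG)
        assert mask[7, 7] > 0
        assert (mask > 0).sum() > 1  # dilation grew the support

    def test_nonnegative_for_random_inputs(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            img = hn.RawFundusImage(rng.integers(0, 256, (24, 24, 3)).astype(np.uint8))
            assert hn.compute_ddog_mask(img, CFG).min() >= 0

    @pytest.mark.parametrize("seed,shape", [(0, (16, 16)), (1, (20, 32)), (2, (32, 17))])
    def test_matches_brute_force_oracle(self, seed, shape):
        rng = np.random.default_rng(seed)
        pixels = rng.integers(0, 256, shape + (3,)).astype(np.uint8)
        img = hn.RawFundusImage(pixels)
        fast = hn.compute_ddog_mask(img, CFG)
        slow = brute_force_ddog(pixels, CFG)
        # blur paths may round a value sitting exactly on .5 differently
        assert np.abs(fast.astype(int) - slow.astype(int)).max() <= 1
        assert (fast != slow).mean() < 0.01


# ---------------------------------------------------------------- fusion


class TestFusion:
    def test_zero_mask_identity(self):
        img = _constant_image(100, (20, 20, 3))
        out = hn.fuse_enhancement(img, np.zeros((20, 20), dtype=np.uint8))
        assert np.array_equal(out.pixels, img.pixels)

    def test_saturation_and_addition(self):
        img = hn.RawFundusImage(np.full((16, 16, 3), 250, dtype=np.uint8))
        out = hn.fuse_enhancement(img, np.full((16, 16), 20, dtype=np.uint8))
        assert out.pixels.max() == out.pixels.min() == 255
        img2 = hn.RawFundusImage(np.full((16, 16, 3), 100, dtype=np.uint8))
        out2 = hn.fuse_enhancement(img2, np.full((16, 16), 37, dtype=np.uint8))
        assert np.all(out2.pixels == 137)

    def test_shape_mismatch_raises(self):
        img = _constant_image(10, (20, 20, 3))
        with pytest.raises(ValueError, match="mask shape"):
            hn.fuse_enhancement(img, np.zeros((10, 10), dtype=np.uint8))

    def test_monotone_and_capped_on_random_images(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            px = rng.integers(0, 256, (16, 16, 3)).astype(np.uint8)
            mask = rng.integers(0, 256, (16, 16)).astype(np.uint8)
            img = hn.RawFundusImage(px)
            fused = hn.fuse_enhancement(img, mask).pixels
            assert np.all(fused >= px)
            assert fused.max() <= 255


# ---------------------------------------------------------------- resize


class TestResize:
    def test_default_output_is_224(self):
        out = hn.resize_bicubic(_constant_image(50, (100, 150, 3)), CFG)
        assert out.pixels.shape == (224, 224, 3)

    def test_identity_at_matching_size(self):
        rng = np.random.default_rng(0)
        px = rng.integers(0, 256, (224, 224, 3)).astype(np.uint8)
        out = hn.resize_bicubic(hn.RawFundusImage(px), CFG)
        assert np.array_equal(out.pixels, px)

    def test_constant_stays_constant(self):
        out = hn.resize_bicubic(_constant_image(77, (60, 90, 3)), CFG)
        assert out.pixels.min() == out.pixels.max() == 77


# ---------------------------------------------------------------- pipeline


class TestPipeline:
    def test_composition_equals_stagewise(self):
        img = hn.generate_image(grade=3, seed=1, size=96)
        raw = hn.RawFundusImage(img.pixels, source_id="p")
        cfg = hn.EnhancementConfig(output_size=64)
        final, inter = hn.enhance_pipeline(raw, cfg, return_intermediates=True)
        manual = hn.resize_bicubic(
            hn.fuse_enhancement(inter["clahe"], inter["ddog"]), cfg)
        assert np.array_equal(final.pixels, manual.pixels)
        assert final.pixels.shape == (64, 64, 3)
        # additive mask can only brighten relative to the CLAHE-only path
        clahe_only = hn.resize_bicubic(inter["clahe"], cfg)
        assert final.pixels.astype(int).mean() >= clahe_only.pixels.astype(int).mean()

    def test_uniform_frame_zero_mask_path(self):
        # a uniform frame passes the crop unchanged, CLAHE keeps it constant,
        # the D-DoG mask vanishes, and the result equals the resized CLAHE image
        a = np.full((80, 80, 3), 140, dtype=np.uint8)
        cfg = hn.EnhancementConfig(output_size=48)
        final, inter = hn.enhance_pipeline(hn.RawFundusImage(a), cfg, return_intermediates=True)
        assert inter["ddog"].max() == 0
        assert np.array_equal(final.pixels, hn.resize_bicubic(inter["clahe"], cfg).pixels)

    def test_error_carries_stage_name(self):
        img = hn.RawFundusImage(np.zeros((32, 32, 3), dtype=np.uint8), source_id="dark")
        with pytest.raises(EmptyFundusError, match=r"\[stage crop\].*dark"):
            hn.enhance_pipeline(img, CFG)
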