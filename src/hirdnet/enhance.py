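"""Field-of-view cropping and CLAHE-D-DoG enhancement of colour fundus images.

The pipeline prepares a raw fundus photograph for grading in five stages:

1. **crop** — threshold away the dark non-retinal border and keep the tight
   bounding box of the largest connected bright region (the retinal disk);
2. **CLAHE** — tile-wise contrast-limited histogram equalization, by default on
   the Lab lightness channel so vessel and lesion hue is preserved;
3. **D-DoG mask** — a difference-of-Gaussians band-pass on the grayscale of the
   CLAHE image (image minus its Gaussian blur, clamped at zero), morphologically
   dilated to gently thicken fine structures such as microaneurysms;
4. **fusion** — the single-channel mask is replicated across RGB and added to
   the CLAHE image with saturation at 255, brightening high-frequency detail;
5. **resize** — bicubic interpolation to the square network input size.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from PIL import Image
from scipy import ndimage
from skimage import color
from skimage.exposure import equalize_adapthist

__all__ = [
    "RawFundusImage",
    "EnhancedFundusImage",
    "EnhancementConfig",
    "EmptyFundusError",
    "ImageTooSmallError",
    "crop_fundus",
    "apply_clahe",
    "compute_ddog_mask",
    "fuse_enhancement",
    "resize_bicubic",
    "enhance_pipeline",
]

#: Rec. 601 luminosity weights used for every RGB -> grayscale conversion.
GRAY_WEIGHTS = np.array([0.299, 0.587, 0.114])


class EmptyFundusError(ValueError):
    """No pixel reaches the background threshold: nothing to crop."""


class ImageTooSmallError(ValueError):
    """Image smaller than the CLAHE tile grid."""


@dataclass
class RawFundusImage:
    """An H×W×3 8-bit colour raster with provenance metadata."""

    pixels: np.ndarray
    source_id: str = ""
    grade: int | None = None

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError(f"{self.source_id}: expected H×W×3 pixels, got {self.pixels.shape}")
        if self.pixels.shape[0] < 16 or self.pixels.shape[1] < 16:
            raise ValueError(f"{self.source_id}: image must be at least 16×16")
        if self.pixels.dtype != np.uint8:
            raise ValueError(f"{self.source_id}: pixels must be 8-bit")
        if self.grade is not None and self.grade not in range(5):
            raise ValueError(f"{self.source_id}: grade must be 0..4, got {self.grade}")

    def grayscale(self) -> np.ndarray:
        """Luminosity grayscale as float64 in [0, 255]."""
        return self.pixels.astype(np.float64) @ GRAY_WEIGHTS


@dataclass
class EnhancedFundusImage:
    """A square, enhanced 8-bit image together with the config that made it."""

    pixels: np.ndarray
    provenance: "EnhancementConfig"
    source_id: str = ""
    grade: int | None = None


@dataclass(frozen=True)
class EnhancementConfig:
    """All preprocessing constants of the enhancement pipeline.

    Defaults follow the reference pipeline: background threshold 10, CLAHE
    clip limit 4.0 on an 8×8 tile grid, a 9×9 Gaussian with σ = 2.0, a 2×2
    dilation element applied once, and a 224-pixel output side.  The CLAHE
    clip limit uses the convention of a multiple of the uniform per-tile
    histogram level.
    """

    background_threshold: int = 10
    clahe_clip_limit: float = 4.0
    clahe_tile_grid: tuple[int, int] = (8, 8)
    clahe_per_channel: bool = False
    gaussian_kernel: int = 9
    gaussian_sigma: float = 2.0
    dilation_element: tuple[int, int] = (2, 2)
    dilation_iterations: int = 1
    output_size: int = 224

    def __post_init__(self):
        if self.gaussian_kernel < 3 or self.gaussian_kernel % 2 == 0:
            raise ValueError("gaussian_kernel must be odd and >= 3")
        if self.clahe_clip_limit <= 0:
            raise ValueError("clahe_clip_limit must be positive")
        if self.output_size <= 0:
            raise ValueError("output_size must be positive")

    @classmethod
    def from_dict(cls, d: dict) -> "EnhancementConfig":
        d = dict(d)
        for key in ("clahe_tile_grid", "dilation_element"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    def with_output_size(self, size: int) -> "EnhancementConfig":
        return replace(self, output_size=size)


def crop_fundus(image: RawFundusImage, cfg: EnhancementConfig = EnhancementConfig()) -> RawFundusImage:
    """Crop to the tight bounding box of the largest connected bright region.

    Pixels of the luminosity grayscale at or above ``background_threshold``
    count as foreground.  Components are 8-connected; ties on area go to the
    component found first in row-major order.  Raises :class:`EmptyFundusError`
    when every pixel is background.
    """
    gray = image.grayscale()
    fg = gray >= cfg.background_threshold
    if not fg.any():
        raise EmptyFundusError(f"empty fundus: no pixel >= {cfg.background_threshold} in {image.source_id!r}")
    labels, nlab = ndimage.label(fg, structure=np.ones((3, 3), dtype=int))
    counts = np.bincount(labels.ravel())[1:]
    best = int(np.argmax(counts)) + 1  # argmax returns the first (row-major) maximum
    rows, cols = np.nonzero(labels == best)
    r0, r1 = rows.min(), rows.max()
    c0, c1 = cols.min(), cols.max()
    return RawFundusImage(image.pixels[r0 : r1 + 1, c0 : c1 + 1].copy(),
                          source_id=image.source_id, grade=image.grade)


def _clahe_channel(channel01: np.ndarray, cfg: EnhancementConfig) -> np.ndarray:
    if channel01.max() == channel01.min():
        # a flat histogram is a fixed point of equalization
        return channel01
    ty, tx = cfg.clahe_tile_grid
    h, w = channel01.shape
    kernel = (max(1, math.ceil(h / ty)), max(1, math.ceil(w / tx)))
    # clip limit given as a multiple of the flat histogram level; the tile-wise
    # equalizer takes it as a fraction of the tile pixel count over 256 bins.
    return equalize_adapthist(channel01, kernel_size=kernel,
                              clip_limit=cfg.clahe_clip_limit / 256.0, nbins=256)


def apply_clahe(image: RawFundusImage, cfg: EnhancementConfig = EnhancementConfig()) -> RawFundusImage:
    """Contrast-limited adaptive histogram equalization.

    By default the lightness channel of the Lab representation is equalized and
    chroma is kept, so the hue of vessels and lesions survives; set
    ``clahe_per_channel`` to equalize each RGB channel independently.
    """
    h, w = image.pixels.shape[:2]
    ty, tx = cfg.clahe_tile_grid
    if h < ty or w < tx:
        raise ImageTooSmallError(
            f"image too small for CLAHE: {h}×{w} < tile grid {ty}×{tx} ({image.source_id!r})")
    if cfg.clahe_per_channel:
        out = np.stack([_clahe_channel(image.pixels[..., c] / 255.0, cfg) for c in range(3)], axis=-1)
        rgb = out
    else:
        lab = color.rgb2lab(image.pixels)
        lab[..., 0] = _clahe_channel(lab[..., 0] / 100.0, cfg) * 100.0
        rgb = np.clip(color.lab2rgb(lab), 0.0, 1.0)
    pixels = np.round(rgb * 255.0).astype(np.uint8)
    return RawFundusImage(pixels, source_id=image.source_id, grade=image.grade)


def gaussian_kernel_1d(size: int, sigma: float) -> np.ndarray:
    """Sampled, normalized 1-D Gaussian of odd length ``size``."""
    c = (size - 1) / 2.0
    x = np.arange(size, dtype=np.float64) - c
    k = np.exp(-(x**2) / (2.0 * sigma**2))
    return k / k.sum()


def _dilate2x2(mask: np.ndarray, iterations: int) -> np.ndarray:
    """Grayscale dilation with a 2×2 element anchored at the top-left pixel."""
    out = mask
    for _ in range(iterations):
        p = np.pad(out, ((0, 1), (0, 1)), mode="edge")
        out = np.maximum.reduce([p[:-1, :-1], p[:-1, 1:], p[1:, :-1], p[1:, 1:]])
    return out


def compute_ddog_mask(clahe_image: RawFundusImage,
                      cfg: EnhancementConfig = EnhancementConfig()) -> np.ndarray:
    """Dilated difference-of-Gaussians mask of the CLAHE image.

    Returns an H×W uint8 mask: the grayscale minus its Gaussian blur, clamped
    at zero (saturating subtraction) and dilated.  Borders are reflected for
    the blur and edge-replicated for the dilation.
    """
    gray = clahe_image.grayscale()
    k = gaussian_kernel_1d(cfg.gaussian_kernel, cfg.gaussian_sigma)
    blur = ndimage.correlate1d(gray, k, axis=0, mode="reflect")
    blur = ndimage.correlate1d(blur, k, axis=1, mode="reflect")
    diff = np.clip(gray - blur, 0.0, 255.0)
    mask = np.round(diff).astype(np.uint8)
    if cfg.dilation_element != (2, 2):
        raise NotImplementedError("only the 2×2 dilation element is supported")
    return _dilate2x2(mask, cfg.dilation_iterations)


def fuse_enhancement(clahe_image: RawFundusImage, mask: np.ndarray) -> RawFundusImage:
    """Replicate the mask across channels and add it with saturation at 255."""
    if mask.shape != clahe_image.pixels.shape[:2]:
        raise ValueError(f"mask shape {mask.shape} does not match image "
                         f"{clahe_image.pixels.shape[:2]} ({clahe_image.source_id!r})")
    fused = clahe_image.pixels.astype(np.int16) + mask.astype(np.int16)[..., None]
    return RawFundusImage(np.minimum(fused, 255).astype(np.uint8),
                          source_id=clahe_image.source_id, grade=clahe_image.grade)


def resize_bicubic(image: RawFundusImage,
                   cfg: EnhancementConfig = EnhancementConfig()) -> EnhancedFundusImage:
    """Bicubic (4×4 neighbourhood) resize to ``output_size`` square."""
    size = cfg.output_size
    pil = Image.fromarray(image.pixels)
    out = np.asarray(pil.resize((size, size), Image.BICUBIC))
    return EnhancedFundusImage(out, provenance=cfg, source_id=image.source_id, grade=image.grade)


_STAGES = ("crop", "clahe", "ddog", "fuse", "resize")


def enhance_pipeline(image: RawFundusImage,
                     cfg: EnhancementConfig = EnhancementConfig(),
                     return_intermediates: bool = False):
    """Run crop → CLAHE → D-DoG → fusion → bicubic resize.

    Stage failures re-raise the original error type with the stage name
    prefixed.  With ``return_intermediates`` the per-stage results are returned
    as a dict alongside the final image.
    """
    inter: dict[str, object] = {}
    stage = "crop"
    try:
        cropped = crop_fundus(image, cfg)
        inter["crop"] = cropped
        stage = "clahe"
        clahe = apply_clahe(cropped, cfg)
        inter["clahe"] = clahe
        stage = "ddog"
        mask = compute_ddog_mask(clahe, cfg)
        inter["ddog"] = mask
        stage = "fuse"
        fused = fuse_enhancement(clahe, mask)
        inter["fuse"] = fused
        stage = "resize"
        enhanced = resize_bicubic(fused, cfg)
    except Exception as exc:  # attach stage name, keep the error type
        raise type(exc)(f"[stage {stage}] {exc}") from exc
    if return_intermediates:
        return enhanced, inter
    return enhanced
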