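"""Gradient-weighted class activation mapping (Grad-CAM).

For a target class c, the gradient of the pre-softmax class score with respect
to the activations of a late convolutional layer is spatially averaged into
per-channel weights α_k; the rectified weighted sum ReLU(Σ_k α_k FM_k) is the
raw localization map.  The map is min-max normalized to [0, 1] (a constant map
becomes all zeros) and bicubically upsampled to the input resolution.

The source layer is the dense connection block's output — the 864-channel
tensor feeding the fourth global-average-pooling layer, captured before the
attention recalibration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import matplotlib
from PIL import Image

from .arch import HIRDNet
from .enhance import EnhancedFundusImage, RawFundusImage

__all__ = ["ClassActivationMap", "channel_weights", "gradcam", "overlay"]


@dataclass
class ClassActivationMap:
    values: np.ndarray  # H×W in [0, 1]
    target_class: int
    source_layer: str = "dcb"


def channel_weights(gradients: np.ndarray) -> np.ndarray:
    """Spatial mean of each channel's gradient: (C, H, W) → (C,).

    A 2-D array is treated as a single channel.
    """
    g = np.asarray(gradients, dtype=np.float64)
    if g.ndim == 2:
        g = g[None]
    if g.ndim != 3:
        raise ValueError(f"expected (C, H, W) gradients, got shape {g.shape}")
    return g.mean(axis=(1, 2))


def _normalize(raw: np.ndarray) -> np.ndarray:
    lo, hi = raw.min(), raw.max()
    if hi - lo <= 0:
        return np.zeros_like(raw)
    return (raw - lo) / (hi - lo)


def _to_float01(image) -> np.ndarray:
    if isinstance(image, (EnhancedFundusImage, RawFundusImage)):
        image = image.pixels
    arr = np.asarray(image)
    if arr.dtype == np.uint8:
        arr = arr.astype(np.float32) / 255.0
    return arr


def gradcam(model: HIRDNet, image, target_class: int,
            upsample: bool = True) -> ClassActivationMap:
    """Class activation map of ``model`` for one image and one class.

    ``image`` is an enhanced fundus image (or raw H×W×3 array) at the model's
    input size.  Raises ``ValueError`` for an invalid class index.
    """
    if not 0 <= target_class < model.cfg.num_classes:
        raise ValueError(f"class index {target_class} outside [0, {model.cfg.num_classes})")
    x = _to_float01(image)
    if x.ndim != 3 or x.shape[2] != 3:
        raise ValueError(f"expected an H×W×3 image, got shape {x.shape}")
    model(x[None], train=False)
    logits = model.last_logits
    seed_grad = np.zeros(logits.shape, dtype=np.float32)
    seed_grad[0, target_class] = 1.0
    logits.backward(seed_grad)
    fm = model.cam_features.data[0]  # (C, h, w)
    grads = model.cam_features.grad[0]
    alpha = channel_weights(grads)
    raw = np.maximum(np.tensordot(alpha, fm.astype(np.float64), axes=(0, 0)), 0.0)
    values = _normalize(raw)
    if upsample:
        target = (x.shape[1], x.shape[0])  # PIL takes (W, H)
        values = np.asarray(Image.fromarray(values.astype(np.float32), mode="F")
                            .resize(target, Image.BICUBIC))
        values = np.clip(values, 0.0, 1.0)
    return ClassActivationMap(values=values, target_class=target_class)


def overlay(image, cam: ClassActivationMap, opacity: float = 0.4) -> RawFundusImage:
    """Colour-map the CAM and alpha-blend it onto the image."""
    if not 0.0 <= opacity <= 1.0:
        raise ValueError("opacity must be in [0, 1]")
    base = _to_float01(image)
    heat = matplotlib.colormaps["jet"](np.clip(cam.values, 0.0, 1.0))[..., :3]
    if heat.shape[:2] != base.shape[:2]:
        heat = np.asarray(Image.fromarray((heat * 255).astype(np.uint8))
                          .resize((base.shape[1], base.shape[0]), Image.BICUBIC)) / 255.0
    blended = (1.0 - opacity) * base + opacity * heat
    pixels = np.clip(np.round(blended * 255.0), 0, 255).astype(np.uint8)
    sid = getattr(image, "source_id", "")
    return RawFundusImage(pixels, source_id=f"{sid}_cam{cam.target_class}" if sid else "")
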