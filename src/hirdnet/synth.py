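"""Deterministic generator of fundus-like labelled test images.

Each image mimics the gross anatomy a grading pipeline relies on: a near-black
border (so field-of-view cropping has something to remove), a roughly circular
orange-toned retinal disk with a radial illumination falloff, a handful of
dark curvilinear vessel-like strokes, and — for grades 1–4 — small bright
"exudate" dots plus dark-red "hemorrhage" blobs whose number grows with the
grade (3·grade exudates, 4·grade hemorrhages).  Lesion positions are drawn
once per (seed, size) and higher grades use a superset of the lower grades'
lesions, so the lesion burden is monotone in grade by construction.

The generator makes no attempt at photorealism; it exists so that every
pipeline stage, the trainer and the explainer are exercisable without any
external download.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataset import LabeledImageSet
from .enhance import RawFundusImage

__all__ = ["SynthSpec", "SynthImage", "generate_image", "generate_dataset"]

_DISK_COLOR = np.array([200.0, 120.0, 40.0])
_VESSEL_COLOR = np.array([95.0, 30.0, 25.0])
_EXUDATE_COLOR = np.array([245.0, 235.0, 130.0])
_HEMORRHAGE_COLOR = np.array([70.0, 15.0, 15.0])

MAX_GRADE = 4
EXUDATES_PER_GRADE = 3
HEMORRHAGES_PER_GRADE = 4


@dataclass(frozen=True)
class SynthSpec:
    """What to generate: per-grade counts, geometry and determinism."""

    image_size: int = 128
    counts: dict[int, int] = field(default_factory=lambda: {g: 10 for g in range(5)})
    seed: int = 0
    lesion_intensity: float = 1.0
    vessel_count: int = 4

    def __post_init__(self):
        if any(n < 0 for n in self.counts.values()):
            raise ValueError("counts must be nonnegative")
        if any(g not in range(5) for g in self.counts):
            raise ValueError("grades must be 0..4")


@dataclass
class SynthImage:
    pixels: np.ndarray  # H×W×3 uint8
    grade: int
    lesion_mask: np.ndarray  # H×W bool


def _paint_disc(img, mask, cy, cx, radius, color, bound):
    h, w = img.shape[:2]
    y0, y1 = max(0, int(cy - radius)), min(h, int(cy + radius) + 1)
    x0, x1 = max(0, int(cx - radius)), min(w, int(cx + radius) + 1)
    yy, xx = np.mgrid[y0:y1, x0:x1]
    hit = ((yy - cy) ** 2 + (xx - cx) ** 2 <= radius**2) & bound[y0:y1, x0:x1]
    img[y0:y1, x0:x1][hit] = color
    if mask is not None:
        mask[y0:y1, x0:x1] |= hit


def generate_image(grade: int, seed: int, size: int = 128,
                   vessel_count: int = 4, lesion_intensity: float = 1.0) -> SynthImage:
    """One synthetic fundus image; byte-identical for identical arguments."""
    if grade not in range(5):
        raise ValueError(f"grade must be 0..4, got {grade}")
    rng = np.random.default_rng([seed & 0x7FFFFFFF, size])
    h = w = size
    cy = cx = size / 2.0
    radius = 0.45 * size

    yy, xx = np.mgrid[0:h, 0:w]
    r2 = (yy - cy) ** 2 + (xx - cx) ** 2
    inside = r2 <= radius**2
    falloff = 1.0 - 0.35 * np.clip(r2 / radius**2, 0.0, 1.0)

    img = rng.integers(0, 4, (h, w, 3)).astype(np.float64)  # border stays < 10
    base = falloff[..., None] * _DISK_COLOR[None, None, :]
    base = base + rng.normal(0.0, 6.0, (h, w, 3))
    img[inside] = base[inside]

    # vessel-like strokes: seeded random walks from near the centre outward
    for _ in range(vessel_count):
        ang = rng.uniform(0, 2 * np.pi)
        py, px = cy + rng.normal(0, 2), cx + rng.normal(0, 2)
        for _ in range(int(0.9 * size)):
            ang += rng.normal(0.0, 0.18)
            py += np.sin(ang)
            px += np.cos(ang)
            iy, ix = int(round(py)), int(round(px))
            if not (0 <= iy < h and 0 <= ix < w) or not inside[iy, ix]:
                break
            img[max(0, iy - 1) : iy + 1, max(0, ix - 1) : ix + 1] = _VESSEL_COLOR

    # lesion candidates drawn for the maximal grade; a grade-g image uses the
    # first 3g exudates and 4g hemorrhages, so grade g+1 strictly extends g
    mask = np.zeros((h, w), dtype=bool)
    gain = np.clip(lesion_intensity, 0.1, 1.5)
    inner = 0.8 * radius
    for count, per_grade, rad_hi, col in (
        (EXUDATES_PER_GRADE * grade, EXUDATES_PER_GRADE, max(2.0, size / 48.0), _EXUDATE_COLOR * gain),
        (HEMORRHAGES_PER_GRADE * grade, HEMORRHAGES_PER_GRADE, max(2.5, size / 40.0), _HEMORRHAGE_COLOR),
    ):
        for k in range(per_grade * MAX_GRADE):
            rho = np.sqrt(rng.uniform(0.01, 1.0)) * inner
            theta = rng.uniform(0, 2 * np.pi)
            ly, lx = cy + rho * np.sin(theta), cx + rho * np.cos(theta)
            lrad = rng.uniform(1.2, rad_hi)
            if k < count:
                _paint_disc(img, mask, ly, lx, lrad, np.clip(col, 0, 255), inside)
    pixels = np.clip(np.round(img), 0, 255).astype(np.uint8)
    return SynthImage(pixels=pixels, grade=grade, lesion_mask=mask)


def generate_dataset(spec: SynthSpec) -> tuple[LabeledImageSet, pd.DataFrame]:
    """A labelled set with exactly the requested per-grade counts, plus a
    manifest frame (``image_path`` is the suggested file name)."""
    items = []
    rows = []
    idx = 0
    for grade in sorted(spec.counts):
        for _ in range(spec.counts[grade]):
            syn = generate_image(grade, seed=spec.seed + 7919 * idx,
                                 size=spec.image_size,
                                 vessel_count=spec.vessel_count,
                                 lesion_intensity=spec.lesion_intensity)
            name = f"synth_{idx:05d}_g{grade}.png"
            items.append((RawFundusImage(syn.pixels, source_id=name, grade=grade), grade))
            rows.append({"image_path": name, "label": grade})
            idx += 1
    return LabeledImageSet(items), pd.DataFrame(rows, columns=["image_path", "label"])
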