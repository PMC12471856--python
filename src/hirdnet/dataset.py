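"""Geometric augmentation, minority oversampling bookkeeping, binary
restructuring, and stratified train/validation/test splitting.

Severity grades use the standard five-level scale: 0 Normal, 1 Mild,
2 Moderate, 3 Severe, 4 Proliferative.  Augmentation applies the four
orientation-preserving-lesion transforms (90° and 270° rotation, horizontal
and vertical flip); together with the original this grows a class five-fold.
"""

from __future__ import annotations

import dataclasses
from collections import Counter
from dataclasses import dataclass, field
from typing import Any, Iterable, Sequence

import numpy as np

__all__ = [
    "GRADE_NAMES",
    "TRANSFORMS",
    "LabeledImageSet",
    "AugmentationPolicy",
    "SplitSpec",
    "augment",
    "augmented_counts",
    "binarize",
    "split",
    "stratified_allocation",
]

GRADE_NAMES = ("Normal", "Mild", "Moderate", "Severe", "Proliferative")

# rotate90 is a 90° counter-clockwise rotation; rotate270 is its inverse.
TRANSFORMS = {
    "rotate90": lambda a: np.rot90(a, 1),
    "rotate270": lambda a: np.rot90(a, 3),
    "horizontal_flip": lambda a: a[:, ::-1],
    "vertical_flip": lambda a: a[::-1, :],
}

_SUFFIX = {"rotate90": "_r90", "rotate270": "_r270",
           "horizontal_flip": "_hf", "vertical_flip": "_vf"}


def _pixels(obj) -> np.ndarray:
    return obj.pixels if hasattr(obj, "pixels") else np.asarray(obj)


def _transformed(obj, name: str):
    arr = np.ascontiguousarray(TRANSFORMS[name](_pixels(obj)))
    if hasattr(obj, "pixels"):
        kwargs = {"pixels": arr}
        if hasattr(obj, "source_id"):
            kwargs["source_id"] = f"{obj.source_id}{_SUFFIX[name]}"
        return dataclasses.replace(obj, **kwargs)
    return arr


@dataclass
class LabeledImageSet:
    """A list of (image, grade) pairs; images are arrays or objects carrying
    a ``pixels`` array."""

    items: list[tuple[Any, int]] = field(default_factory=list)

    def __post_init__(self):
        bad = {g for _, g in self.items if g not in range(5)}
        if bad:
            raise ValueError(f"grades must be in 0..4, got {sorted(bad)}")

    @property
    def class_counts(self) -> dict[int, int]:
        return dict(Counter(g for _, g in self.items))

    def __len__(self) -> int:
        return len(self.items)

    def subset(self, indices: Iterable[int]) -> "LabeledImageSet":
        return LabeledImageSet([self.items[i] for i in indices])


@dataclass(frozen=True)
class AugmentationPolicy:
    """Which transforms to apply and to which severity classes."""

    transforms: tuple[str, ...] = ("rotate90", "rotate270", "horizontal_flip", "vertical_flip")
    target_classes: tuple[int, ...] | str = "all"
    keep_original: bool = True

    def __post_init__(self):
        if not self.transforms:
            raise ValueError("transforms must be non-empty")
        if len(set(self.transforms)) != len(self.transforms):
            raise ValueError("duplicate transforms")
        unknown = set(self.transforms) - set(TRANSFORMS)
        if unknown:
            raise ValueError(f"unknown transforms: {sorted(unknown)}")

    def targets(self, grade: int) -> bool:
        return self.target_classes == "all" or grade in self.target_classes


#: Minority-oversampling policy used for the strongly imbalanced datasets:
#: augment only Mild, Severe and Proliferative.
MINORITY_POLICY = AugmentationPolicy(target_classes=(1, 3, 4))


def augment(image_set: LabeledImageSet, policy: AugmentationPolicy) -> LabeledImageSet:
    """Emit, per targeted item, the original (optional) plus one image per
    transform; untargeted classes pass through unchanged."""
    out: list[tuple[Any, int]] = []
    for obj, grade in image_set.items:
        if policy.targets(grade):
            if policy.keep_original:
                out.append((obj, grade))
            for name in policy.transforms:
                out.append((_transformed(obj, name), grade))
        else:
            out.append((obj, grade))
    return LabeledImageSet(out)


def augmented_counts(class_counts: dict[int, int], policy: AugmentationPolicy) -> dict[int, int]:
    """Pure bookkeeping form of :func:`augment` on per-class counts."""
    factor = len(policy.transforms) + (1 if policy.keep_original else 0)
    return {g: n * factor if policy.targets(g) else n for g, n in class_counts.items()}


def binarize(image_set: LabeledImageSet) -> LabeledImageSet:
    """Collapse severity grades to a screening label: 0 Normal, 1–4 Abnormal."""
    return LabeledImageSet([(obj, 0 if g == 0 else 1) for obj, g in image_set.items])


@dataclass(frozen=True)
class SplitSpec:
    """Train/validation/test fractions (default 70/10/20), seeded."""

    train: float = 0.70
    val: float = 0.10
    test: float = 0.20
    seed: int = 0
    stratified: bool = True

    def __post_init__(self):
        for f in (self.train, self.val, self.test):
            if not 0.0 <= f <= 1.0:
                raise ValueError("fractions must lie in [0, 1]")
        if abs(self.train + self.val + self.test - 1.0) > 1e-9:
            raise ValueError("fractions must sum to 1")


def _round_half_away(x: float) -> int:
    return int(np.floor(x + 0.5)) if x >= 0 else -int(np.floor(-x + 0.5))


def stratified_allocation(n: int, spec: SplitSpec) -> tuple[int, int, int]:
    """Per-class (train, val, test) sizes: test and val round half away from
    zero, the remainder goes to train."""
    n_test = _round_half_away(spec.test * n)
    n_val = _round_half_away(spec.val * n)
    n_train = n - n_test - n_val
    if n_train < 0:
        raise ValueError("rounding exceeded class size")
    return n_train, n_val, n_test


def split(image_set: LabeledImageSet, spec: SplitSpec
          ) -> tuple[LabeledImageSet, LabeledImageSet, LabeledImageSet]:
    """Partition into disjoint train/val/test sets, deterministic per seed.

    With stratification each class is shuffled and allocated separately, so
    per-class test counts equal round(test fraction × class count).
    """
    rng = np.random.default_rng(spec.seed)
    n_parts = sum(1 for f in (spec.train, spec.val, spec.test) if f > 0)
    train_idx: list[int] = []
    val_idx: list[int] = []
    test_idx: list[int] = []
    if spec.stratified:
        by_class: dict[int, list[int]] = {}
        for i, (_, g) in enumerate(image_set.items):
            by_class.setdefault(g, []).append(i)
        for g in sorted(by_class):
            idx = np.array(by_class[g])
            if len(idx) < n_parts:
                raise ValueError(
                    f"class {GRADE_NAMES[g] if g < 5 else g} has {len(idx)} items, "
                    f"fewer than the {n_parts} split parts")
            rng.shuffle(idx)
            n_train, n_val, n_test = stratified_allocation(len(idx), spec)
            test_idx.extend(idx[:n_test])
            val_idx.extend(idx[n_test : n_test + n_val])
            train_idx.extend(idx[n_test + n_val :])
    else:
        idx = rng.permutation(len(image_set))
        n_train, n_val, n_test = stratified_allocation(len(idx), spec)
        test_idx = list(idx[:n_test])
        val_idx = list(idx[n_test : n_test + n_val])
        train_idx = list(idx[n_test + n_val :])
    return (image_set.subset(train_idx), image_set.subset(val_idx), image_set.subset(test_idx))
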