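"""Reading and writing images and CSV manifests.

A manifest is a CSV with header ``image_path,label`` (and optionally
``split``), paths relative to the manifest's own directory unless absolute.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .dataset import LabeledImageSet
from .enhance import RawFundusImage

__all__ = ["load_image", "save_image", "read_manifest", "write_manifest",
           "load_set", "save_set"]


def load_image(path, grade: int | None = None) -> RawFundusImage:
    path = Path(path)
    arr = np.asarray(Image.open(path).convert("RGB"))
    return RawFundusImage(arr, source_id=path.stem, grade=grade)


def save_image(path, image) -> None:
    arr = image.pixels if hasattr(image, "pixels") else np.asarray(image)
    Image.fromarray(arr).save(path)


def read_manifest(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = {"image_path", "label"} - set(df.columns)
    if missing:
        raise ValueError(f"manifest {path} lacks columns: {sorted(missing)}")
    return df


def write_manifest(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def load_set(manifest_path, split: str | None = None) -> LabeledImageSet:
    """Load every image of a manifest (optionally one split) into memory."""
    manifest_path = Path(manifest_path)
    df = read_manifest(manifest_path)
    if split is not None:
        if "split" not in df.columns:
            raise ValueError("manifest has no split column; run the split step first")
        df = df[df["split"] == split]
    items = []
    for row in df.itertuples(index=False):
        p = Path(row.image_path)
        if not p.is_absolute():
            p = manifest_path.parent / p
        img = load_image(p, grade=int(row.label))
        items.append((img, int(row.label)))
    return LabeledImageSet(items)


def save_set(image_set: LabeledImageSet, out_dir, manifest_name: str = "manifest.csv") -> Path:
    """Write every image as PNG plus a manifest; returns the manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, (obj, grade) in enumerate(image_set.items):
        name = getattr(obj, "source_id", "") or f"img_{i:05d}"
        if not name.endswith(".png"):
            name = f"{name}.png"
        save_image(out_dir / name, obj)
        rows.append({"image_path": name, "label": grade})
    manifest = out_dir / manifest_name
    write_manifest(pd.DataFrame(rows, columns=["image_path", "label"]), manifest)
    return manifest
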