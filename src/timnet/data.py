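"""Dataset folder reading.

Layout: ``<root>/images/``, ``<root>/masks/`` and optionally ``<root>/fov/``
holding PNG/TIFF/JPEG rasters matched by file stem.  Images are returned as
(3, H, W) float arrays in [0, 1] (grayscale replicated to three channels,
bilinear resize); masks and FOV as (H, W) {0,1} arrays (nearest-neighbour
resize, binarised at 127/255).  Items come back in lexicographic stem
order; stems missing a mask are skipped with a warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image

from .exceptions import ValidationError

__all__ = ["DatasetItem", "load_dataset", "read_image", "read_mask", "write_mask", "write_prob"]

RASTER_SUFFIXES = (".png", ".tif", ".tiff", ".jpg", ".jpeg")


@dataclass
class DatasetItem:
    stem: str
    image: np.ndarray  # (3, H, W) float32 in [0, 1]
    mask: np.ndarray  # (H, W) uint8 {0, 1}
    fov: np.ndarray | None = None  # (H, W) uint8 {0, 1}


def read_image(path, input_size: int | None = None) -> np.ndarray:
    img = Image.open(path).convert("RGB")
    if input_size is not None and img.size != (input_size, input_size):
        img = img.resize((input_size, input_size), Image.BILINEAR)
    arr = np.asarray(img, dtype=np.float32) / 255.0
    return arr.transpose(2, 0, 1)


def read_mask(path, input_size: int | None = None) -> np.ndarray:
    img = Image.open(path).convert("L")
    if input_size is not None and img.size != (input_size, input_size):
        img = img.resize((input_size, input_size), Image.NEAREST)
    return (np.asarray(img) > 127).astype(np.uint8)


def write_mask(path, mask: np.ndarray) -> None:
    Image.fromarray((np.asarray(mask) > 0).astype(np.uint8) * 255).save(path)


def write_prob(path, prob: np.ndarray) -> None:
    Image.fromarray(np.round(np.clip(prob, 0, 1) * 255).astype(np.uint8)).save(path)


def _index(folder: Path) -> dict[str, Path]:
    return {p.stem: p for p in sorted(folder.iterdir()) if p.suffix.lower() in RASTER_SUFFIXES}


def load_dataset(root, input_size: int | None = None) -> list[DatasetItem]:
    root = Path(root)
    img_dir, mask_dir, fov_dir = root / "images", root / "masks", root / "fov"
    if not img_dir.is_dir() or not mask_dir.is_dir():
        raise ValidationError(f"dataset at {root} must contain images/ and masks/")
    images = _index(img_dir)
    masks = _index(mask_dir)
    fovs = _index(fov_dir) if fov_dir.is_dir() else {}
    matched = sorted(images.keys() & masks.keys())
    skipped = sorted(images.keys() ^ masks.keys())
    if skipped:
        warnings.warn(f"skipping unmatched stems: {skipped}", stacklevel=2)
    if not matched:
        raise ValidationError(f"no matched image/mask pairs under {root}")
    items = []
    for stem in matched:
        items.append(
            DatasetItem(
                stem=stem,
                image=read_image(images[stem], input_size),
                mask=read_mask(masks[stem], input_size),
                fov=read_mask(fovs[stem], input_size) if stem in fovs else None,
            )
        )
    return items
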