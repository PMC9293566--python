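"""Seeded retinal-fundus phantoms: (image, vessel mask, FOV) triples.

The generator emulates the geometry of fundus photographs well enough to
exercise every pipeline stage without real data: a circular field of view
(radius 0.48 x size), a brighter textured disc, and dark branching vessel
trees grown as random walks from the disc margin whose width shrinks at
each bifurcation.  It makes no attempt at photo-realism - no optic disc,
macula, lesions or camera effects.

Every output is fully determined by the seed.  Vessels are rasterised with
a soft (anti-aliased) brush and thresholded at 0.5 coverage to the binary
mask; the image is a smooth radial background minus a blurred copy of the
vessel mask scaled by the contrast, plus white Gaussian noise, clipped to
[0, 1] and zeroed outside the FOV.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image
from scipy.ndimage import gaussian_filter

from .exceptions import ValidationError

__all__ = ["PhantomParams", "Phantom", "generate_phantom", "generate_dataset"]

FOV_RADIUS_FRACTION = 0.48
MAX_TURN_DEG = 25.0  # random-walk heading jitter per step
BRANCH_ANGLE_DEG = 35.0  # mean separation of the two children at a fork


@dataclass
class PhantomParams:
    size: int = 64
    n_trees: int = 3
    branch_prob: float = 0.10
    width_root: float = 2.0
    width_decay: float = 0.85
    vessel_contrast: float = 0.5
    noise_sigma: float = 0.02
    seed: int = 0

    def __post_init__(self):
        if self.size % 32:
            raise ValidationError(f"size must be divisible by 32, got {self.size}")
        if self.n_trees > 0 and self.width_root < 1:
            raise ValidationError("width_root must be at least 1 pixel")
        if not 0 < self.width_decay <= 1:
            raise ValidationError("width_decay must be in (0, 1]")
        if not 0 <= self.branch_prob <= 1:
            raise ValidationError("branch_prob must be in [0, 1]")


@dataclass
class Phantom:
    image: np.ndarray  # (H, W) float in [0, 1]
    mask: np.ndarray  # (H, W) uint8 {0, 1}
    fov: np.ndarray  # (H, W) uint8 {0, 1}


def _fov_disc(size: int) -> np.ndarray:
    c = (size - 1) / 2.0
    yy, xx = np.mgrid[0:size, 0:size]
    return ((yy - c) ** 2 + (xx - c) ** 2 <= (FOV_RADIUS_FRACTION * size) ** 2).astype(np.uint8)


def _stamp(canvas: np.ndarray, y: float, x: float, radius: float) -> None:
    """Soft-edged disc brush: coverage 1 inside, linear falloff over 1 px.

    The radius is floored at 0.8 px so that after thresholding at 0.5 every
    stamp covers its nearest pixels and consecutive stamps stay 8-connected.
    """
    radius = max(radius, 0.8)
    size = canvas.shape[0]
    r_ext = int(np.ceil(radius + 1.5))
    y0, y1 = max(0, int(y) - r_ext), min(size, int(y) + r_ext + 1)
    x0, x1 = max(0, int(x) - r_ext), min(size, int(x) + r_ext + 1)
    if y0 >= y1 or x0 >= x1:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1]
    d = np.sqrt((yy - y) ** 2 + (xx - x) ** 2)
    cover = np.clip(radius + 0.5 - d, 0.0, 1.0)
    np.maximum(canvas[y0:y1, x0:x1], cover, out=canvas[y0:y1, x0:x1])


def _grow_tree(rng: np.random.Generator, p: PhantomParams) -> np.ndarray:
    """Rasterise one branching random-walk tree onto a coverage canvas."""
    size = p.size
    c = (size - 1) / 2.0
    r_fov = FOV_RADIUS_FRACTION * size
    canvas = np.zeros((size, size), dtype=np.float32)

    theta = rng.uniform(0, 2 * np.pi)
    start = np.array([c + 0.92 * r_fov * np.sin(theta), c + 0.92 * r_fov * np.cos(theta)])
    heading = theta + np.pi + rng.uniform(-0.4, 0.4)  # roughly toward centre
    queue = [(start, heading, float(p.width_root))]
    max_segments = 64
    segments = 0
    while queue and segments < max_segments:
        pos, head, width = queue.pop()
        segments += 1
        steps = int(rng.integers(8, 20) * max(1.0, size / 64))
        for _ in range(steps):
            _stamp(canvas, pos[0], pos[1], width / 2.0)
            head += np.deg2rad(rng.uniform(-MAX_TURN_DEG, MAX_TURN_DEG))
            step = max(0.75, 0.5 * width)
            pos = pos + step * np.array([np.sin(head), np.cos(head)])
            if (pos[0] - c) ** 2 + (pos[1] - c) ** 2 > (0.97 * r_fov) ** 2:
                break
            if width >= 1.0 and rng.random() < p.branch_prob:
                child_w = width * p.width_decay
                split = np.deg2rad(BRANCH_ANGLE_DEG * rng.uniform(0.7, 1.3))
                queue.append((pos.copy(), head + split / 2, child_w))
                head -= split / 2
                width = child_w
        else:
            continue
    return canvas


def generate_phantom(p: PhantomParams) -> Phantom:
    """Draw one phantom; bit-reproducible for a fixed ``p.seed``."""
    if p.n_trees == 0 or p.vessel_contrast == 0:
        warnings.warn("degenerate phantom parameters (no trees or zero contrast)", stacklevel=2)
    rng = np.random.default_rng(p.seed)
    size = p.size
    fov = _fov_disc(size)

    coverage = np.zeros((size, size), dtype=np.float32)
    for _ in range(p.n_trees):
        np.maximum(coverage, _grow_tree(rng, p), out=coverage)
    mask = ((coverage >= 0.5) & (fov == 1)).astype(np.uint8)

    c = (size - 1) / 2.0
    yy, xx = np.mgrid[0:size, 0:size]
    rad2 = ((yy - c) ** 2 + (xx - c) ** 2) / (FOV_RADIUS_FRACTION * size) ** 2
    background = 0.75 - 0.20 * rad2
    texture = gaussian_filter(rng.normal(0.0, 1.0, (size, size)), sigma=size / 12.0)
    tex_std = texture.std()
    if tex_std > 0:
        background = background + 0.03 * texture / tex_std
    image = background - p.vessel_contrast * gaussian_filter(mask.astype(np.float64), sigma=0.6)
    image = image + rng.normal(0.0, p.noise_sigma, (size, size))
    image = np.clip(image, 0.0, 1.0) * fov
    return Phantom(image=image.astype(np.float64), mask=mask, fov=fov)


def generate_dataset(seed: int, n: int, p: PhantomParams, out_dir, force: bool = False) -> list[str]:
    """Write n phantoms in the dataset folder layout (images/, masks/, fov/).

    Item i is generated with seed ``seed + i``.  Returns the stems written.
    Refuses a non-empty target directory unless ``force`` is set.
    """
    out = Path(out_dir)
    if out.exists() and any(out.iterdir()) and not force:
        raise FileExistsError(f"{out} exists and is not empty (use force=True to overwrite)")
    stems = []
    for sub in ("images", "masks", "fov"):
        (out / sub).mkdir(parents=True, exist_ok=True)
    for i in range(n):
        params = PhantomParams(**{**p.__dict__, "seed": seed + i})
        ph = generate_phantom(params)
        stem = f"phantom_{i:03d}"
        Image.fromarray(np.round(ph.image * 255).astype(np.uint8)).save(out / "images" / f"{stem}.png")
        Image.fromarray(ph.mask * 255).save(out / "masks" / f"{stem}.png")
        Image.fromarray(ph.fov * 255).save(out / "fov" / f"{stem}.png")
        stems.append(stem)
    return stems
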