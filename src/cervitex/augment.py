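"""Geometric augmentation of labeled image sets.

Each augmented copy applies, in order: a random rotation within
+/- rotation_deg, a shear sampled within +/- shear, translations sampled
within the shift fractions of the image size, and independent coin-flip
horizontal/vertical mirrors.  Out-of-frame pixels are filled with constant
0.  Labels, modality and a provenance pointer to the source are inherited.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage

from .exceptions import ManifestError, ParameterError
from .image_prep import RGBImage

__all__ = ["AugmentConfig", "augment_image", "augment_dataset"]


@dataclass(frozen=True)
class AugmentConfig:
    """Augmentation operator magnitudes (maxima of uniform random draws)."""

    rotation_deg: float = 15.0
    width_shift: float = 0.2
    height_shift: float = 0.2
    shear: float = 0.2
    horizontal_flip: bool = True
    vertical_flip: bool = True
    n_per_image: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("width_shift", "height_shift", "shear"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ParameterError(f"{name} must lie in [0, 1], got {v}")
        if self.rotation_deg < 0:
            raise ParameterError("rotation_deg must be >= 0")
        if self.n_per_image < 0:
            raise ParameterError("n_per_image must be >= 0")


def _random_affine(img: RGBImage, cfg: AugmentConfig, rng: np.random.Generator):
    h, w = img.shape
    angle = np.radians(rng.uniform(-cfg.rotation_deg, cfg.rotation_deg))
    shear = rng.uniform(-cfg.shear, cfg.shear)
    ty = rng.uniform(-cfg.height_shift, cfg.height_shift) * h
    tx = rng.uniform(-cfg.width_shift, cfg.width_shift) * w
    flip_h = cfg.horizontal_flip and rng.random() < 0.5
    flip_v = cfg.vertical_flip and rng.random() < 0.5

    ca, sa = np.cos(angle), np.sin(angle)
    rot = np.array([[ca, -sa], [sa, ca]])
    shr = np.array([[1.0, 0.0], [shear, 1.0]])  # shear columns with row index
    A = shr @ rot
    center = np.array([(h - 1) / 2.0, (w - 1) / 2.0])
    # forward map: y = A (x - c) + c + t  =>  x = A^-1 (y - c - t) + c
    Ainv = np.linalg.inv(A)
    offset = center - Ainv @ (center + np.array([ty, tx]))

    out = np.empty_like(img.pixels)
    for ch in range(3):
        out[:, :, ch] = ndimage.affine_transform(
            img.pixels[:, :, ch].astype(np.float64),
            Ainv,
            offset=offset,
            order=1,
            mode="constant",
            cval=0.0,
        ).round().clip(0, 255).astype(np.uint8)
    if flip_h:
        out = out[:, ::-1, :]
    if flip_v:
        out = out[::-1, :, :]
    return out


def augment_image(
    img: RGBImage, cfg: AugmentConfig, rng: np.random.Generator
) -> list[RGBImage]:
    """Produce ``cfg.n_per_image`` randomly transformed copies of one image."""
    copies = []
    for k in range(cfg.n_per_image):
        px = _random_affine(img, cfg, rng)
        copies.append(
            RGBImage(
                pixels=px,
                label=img.label,
                modality=img.modality,
                source_id=f"{img.source_id}#aug{k}",
            )
        )
    return copies


def augment_dataset(
    dataset: Sequence[RGBImage], cfg: AugmentConfig
) -> tuple[list[RGBImage], dict[str, int]]:
    """Originals plus augmented copies; returns (images, per-class counts).

    Output size is ``len(dataset) * (1 + n_per_image)``.  Determinism: the
    same (dataset, cfg) pair always yields identical output, driven by
    ``cfg.seed``.
    """
    for img in dataset:
        if img.label is None:
            raise ManifestError(
                f"image {img.source_id!r} has no label; augmentation requires labels"
            )
    rng = np.random.default_rng(cfg.seed)
    out: list[RGBImage] = []
    counts: dict[str, int] = {}
    for img in dataset:
        group = [img] + augment_image(img, cfg, rng)
        out.extend(group)
        counts[img.label] = counts.get(img.label, 0) + len(group)
    return out, counts
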