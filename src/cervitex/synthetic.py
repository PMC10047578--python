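"""Synthetic two-class texture datasets and hand-checkable toy matrices.

No public cervigram compilation with labels is deposited anywhere, so the
pipeline is exercised on generated textures whose two classes differ in
exactly the statistics the three extractors measure: the correlation length
of a smoothed noise field (run-length and co-occurrence structure), the
amplitude of an oriented sinusoidal grating (co-occurrence contrast), and
the grating's orientation (edge-orientation content for HOG).

Generation is a pure function of (specs, n, size, seed).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

from .exceptions import ParameterError
from .image_prep import RGBImage

__all__ = [
    "TextureClassSpec",
    "NORMAL_SPEC",
    "ABNORMAL_SPEC",
    "make_texture_image",
    "make_texture_dataset",
    "ToyMatrix",
    "toy_matrix_catalog",
]

#: Amplitude (gray levels) of the smoothed noise field.
NOISE_AMPLITUDE = 25.0
#: Wavelength of the oriented grating, pixels.
GRATING_WAVELENGTH = 16.0
#: Standard deviation of per-channel sensor noise, gray levels.
CHANNEL_NOISE_SD = 2.0


@dataclass(frozen=True)
class TextureClassSpec:
    """Controllable texture statistics for one class."""

    correlation_length: float = 1.0
    contrast_scale: float = 5.0
    orientation_deg: float = 0.0
    base_intensity: tuple[float, float, float] = (140.0, 110.0, 100.0)

    def __post_init__(self) -> None:
        if self.correlation_length < 1:
            raise ParameterError("correlation_length must be >= 1 pixel")


#: Default class conditions: fine-grained, low-contrast, horizontal structure
#: versus coarse, high-contrast, vertical structure.
NORMAL_SPEC = TextureClassSpec(
    correlation_length=1.0,
    contrast_scale=5.0,
    orientation_deg=0.0,
    base_intensity=(150.0, 115.0, 105.0),
)
ABNORMAL_SPEC = TextureClassSpec(
    correlation_length=8.0,
    contrast_scale=40.0,
    orientation_deg=90.0,
    base_intensity=(160.0, 125.0, 110.0),
)


def make_texture_image(
    spec: TextureClassSpec,
    size: tuple[int, int],
    rng: np.random.Generator,
    label: str,
    source_id: str,
) -> RGBImage:
    """One image: smoothed noise + oriented grating + per-channel sensor noise."""
    h, w = size
    noise = gaussian_filter(rng.standard_normal((h, w)), spec.correlation_length)
    sd = noise.std()
    field = NOISE_AMPLITUDE * (noise / sd if sd > 0 else noise)

    rows, cols = np.mgrid[0:h, 0:w].astype(np.float64)
    ang = np.radians(spec.orientation_deg)
    # grating stripes run along orientation_deg; phase varies across images
    coord = cols * np.cos(ang) + rows * np.sin(ang)
    phase = rng.uniform(0, 2 * np.pi)
    grating = spec.contrast_scale * np.sin(2 * np.pi * coord / GRATING_WAVELENGTH + phase)

    px = np.empty((h, w, 3))
    for c in range(3):
        px[:, :, c] = (
            spec.base_intensity[c]
            + field
            + grating
            + CHANNEL_NOISE_SD * rng.standard_normal((h, w))
        )
    return RGBImage(
        pixels=np.clip(px, 0, 255).round().astype(np.uint8),
        label=label,
        source_id=source_id,
    )


def make_texture_dataset(
    n_per_class: int = 100,
    spec_a: TextureClassSpec = NORMAL_SPEC,
    spec_b: TextureClassSpec = ABNORMAL_SPEC,
    image_size: tuple[int, int] = (256, 128),
    seed: int = 0,
) -> list[RGBImage]:
    """Labeled two-class image list; class A is normal, class B abnormal."""
    if n_per_class < 1:
        raise ParameterError("n_per_class must be >= 1")
    rng = np.random.default_rng(seed)
    images: list[RGBImage] = []
    for i in range(n_per_class):
        images.append(
            make_texture_image(spec_a, image_size, rng, "normal", f"normal_{i:04d}")
        )
    for i in range(n_per_class):
        images.append(
            make_texture_image(spec_b, image_size, rng, "abnormal", f"abnormal_{i:04d}")
        )
    return images


@dataclass(frozen=True)
class ToyMatrix:
    """A tiny integer grid with brute-force-verified texture statistics.

    ``expected`` maps block -> direction (degrees) -> statistic -> value.
    Tests must regenerate every stored value with the independent
    enumeration oracles; the catalog is never trusted on its own.
    """

    name: str
    grid: np.ndarray
    ng: int
    expected: dict


def toy_matrix_catalog() -> dict[str, ToyMatrix]:
    """Named <= 6x6 grids used across the unit tests, with oracle values."""
    constant = ToyMatrix(
        name="constant",
        grid=np.ones((4, 4), dtype=np.int64),
        ng=1,
        expected={
            "glrlm": {0: {"rp": 0.25, "sre": 1 / 16, "lre": 16.0, "gln": 4.0}},
            "glcm": {
                0: {
                    "energy": 1.0,
                    "entropy": 0.0,
                    "max_probability": 1.0,
                    "contrast": 0.0,
                    "homogeneity1": 1.0,
                }
            },
        },
    )
    checker = np.indices((4, 4)).sum(axis=0) % 2 + 1
    checkerboard = ToyMatrix(
        name="checkerboard",
        grid=checker.astype(np.int64),
        ng=2,
        expected={
            "glrlm": {0: {"sre": 1.0, "lre": 1.0, "rp": 1.0}},
            "glcm": {0: {"contrast": 1.0, "dissimilarity": 1.0, "homogeneity1": 0.5}},
        },
    )
    single_row = ToyMatrix(
        name="single_row_run",
        grid=np.array([[5, 5, 5, 2]], dtype=np.int64),
        ng=5,
        expected={"glrlm": {0: {"nr": 2.0, "rp": 0.5}}},
    )
    pair = ToyMatrix(
        name="pair_2x2",
        grid=np.array([[1, 2], [1, 2]], dtype=np.int64),
        ng=2,
        expected={"glcm": {0: {"max_probability": 0.5, "contrast": 1.0}}},
    )
    ramp = ToyMatrix(
        name="ramp",
        grid=np.tile(np.arange(1, 5, dtype=np.int64), (4, 1)),
        ng=4,
        expected={
            "glrlm": {0: {"sre": 1.0, "lre": 1.0, "rp": 1.0}, 90: {"rp": 0.25}},
            "glcm": {0: {"contrast": 1.0, "dissimilarity": 1.0}},
        },
    )
    return {t.name: t for t in (constant, checkerboard, single_row, pair, ramp)}
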