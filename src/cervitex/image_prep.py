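"""Image loading, channel splitting, gray-level quantization and the HOG window.

Colposcopy frames arrive as ordinary RGB rasters.  Texture matrices (run
length and co-occurrence) are built per colour channel after quantizing the
intensities onto a small integer alphabet ``1..Ng``; the oriented-gradient
descriptor instead works on a fixed-size grayscale window cut from the frame
centre, where the cervix sits in standard colposcopy framing.

Axis convention: arrays are indexed ``(row, column) = (height, width)``.
Sizes quoted in the width x height style of the HOG literature ("64 x 128",
"100 x 200") therefore correspond to arrays of shape ``(128, 64)`` and
``(200, 100)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from PIL import Image, UnidentifiedImageError
from skimage.transform import resize as _sk_resize

from .exceptions import DecodeError, ParameterError

__all__ = [
    "RGBImage",
    "QuantizedChannel",
    "GrayWindow",
    "LUMA_WEIGHTS",
    "HOG_WINDOW_SHAPE",
    "HOG_CROP_SHAPE",
    "load_image",
    "split_channels",
    "quantize",
    "prepare_hog_window",
]

#: ITU-R BT.601 luma weights for R, G, B.
LUMA_WEIGHTS = (0.299, 0.587, 0.114)

#: Grayscale window fed to the HOG descriptor, as (rows, cols) = 128 tall x 64 wide.
HOG_WINDOW_SHAPE = (128, 64)

#: Centered crop taken before the final resize, as (rows, cols) = 200 tall x 100 wide.
HOG_CROP_SHAPE = (200, 100)

MODALITIES = ("raw", "acetowhite", "green_filter", "iodine")
LABELS = ("normal", "abnormal")


@dataclass
class RGBImage:
    """A 3-channel raster with an optional class label and modality tag.

    ``pixels`` is ``(H, W, 3)`` uint8; ``H, W >= 8``.
    """

    pixels: np.ndarray
    label: Optional[str] = None
    modality: Optional[str] = None
    source_id: str = ""

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ParameterError(
                f"RGBImage requires an (H, W, 3) array, got shape {px.shape}"
            )
        if px.shape[0] < 8 or px.shape[1] < 8:
            raise ParameterError(
                f"RGBImage requires H >= 8 and W >= 8, got {px.shape[:2]}"
            )
        if px.dtype != np.uint8:
            if px.min() < 0 or px.max() > 255:
                raise ParameterError("pixel intensities must lie in [0, 255]")
            px = px.astype(np.uint8)
        self.pixels = px
        if self.label is not None and self.label not in LABELS:
            raise ParameterError(f"label must be one of {LABELS}, got {self.label!r}")
        if self.modality is not None and self.modality not in MODALITIES:
            raise ParameterError(
                f"modality must be one of {MODALITIES}, got {self.modality!r}"
            )

    @property
    def shape(self) -> tuple[int, int]:
        """(H, W) of the raster."""
        return self.pixels.shape[:2]


@dataclass
class QuantizedChannel:
    """A single channel mapped onto integer gray levels ``1..ng``."""

    grid: np.ndarray
    ng: int

    def __post_init__(self) -> None:
        g = np.asarray(self.grid)
        if g.ndim != 2:
            raise ParameterError("QuantizedChannel grid must be 2-D")
        if self.ng < 1:
            raise ParameterError(f"ng must be >= 1, got {self.ng}")
        if g.size and (g.min() < 1 or g.max() > self.ng):
            raise ParameterError("quantized levels must lie in [1, ng]")
        self.grid = g.astype(np.int64)


@dataclass
class GrayWindow:
    """The 128x64 grayscale window (values in [0, 1]) fed to HOG."""

    grid: np.ndarray

    def __post_init__(self) -> None:
        g = np.asarray(self.grid, dtype=np.float64)
        if g.shape != HOG_WINDOW_SHAPE:
            raise ParameterError(
                f"GrayWindow must have shape {HOG_WINDOW_SHAPE}, got {g.shape}"
            )
        self.grid = np.clip(g, 0.0, 1.0)


def load_image(path, label=None, modality=None, source_id=None) -> RGBImage:
    """Decode a PNG/JPEG file into an :class:`RGBImage`.

    Grayscale sources are replicated to three channels; an alpha channel is
    discarded.  Raises :class:`DecodeError` naming the path on failure.
    """
    try:
        with Image.open(path) as im:
            im = im.convert("RGB")
            px = np.asarray(im, dtype=np.uint8)
    except (UnidentifiedImageError, OSError, ValueError) as exc:
        raise DecodeError(f"cannot decode image file {path!s}: {exc}") from exc
    return RGBImage(
        pixels=px,
        label=label,
        modality=modality,
        source_id=str(path) if source_id is None else source_id,
    )


def split_channels(img: RGBImage) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Return the (R, G, B) planes of an image as three H x W grids."""
    px = img.pixels
    return px[:, :, 0].copy(), px[:, :, 1].copy(), px[:, :, 2].copy()


def quantize(channel: np.ndarray, ng: int = 8) -> QuantizedChannel:
    """Linearly rescale a channel's ``[min, max]`` range onto levels ``1..ng``.

    The mapping is monotone; a constant channel maps entirely to level 1.
    """
    if ng < 1:
        raise ParameterError(f"ng must be >= 1, got {ng}")
    ch = np.asarray(channel, dtype=np.float64)
    if ch.ndim != 2 or ch.size == 0:
        raise ParameterError("channel must be a nonempty 2-D grid")
    lo, hi = ch.min(), ch.max()
    if hi == lo:
        levels = np.ones(ch.shape, dtype=np.int64)
    else:
        t = (ch - lo) / (hi - lo)
        levels = np.minimum((t * ng).astype(np.int64), ng - 1) + 1
    return QuantizedChannel(grid=levels, ng=ng)


def _to_gray(img: RGBImage) -> np.ndarray:
    wr, wg, wb = LUMA_WEIGHTS
    px = img.pixels.astype(np.float64)
    return (wr * px[:, :, 0] + wg * px[:, :, 1] + wb * px[:, :, 2]) / 255.0


def _center_crop(arr: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    h, w = arr.shape
    ch, cw = shape
    r0 = (h - ch) // 2
    c0 = (w - cw) // 2
    return arr[r0 : r0 + ch, c0 : c0 + cw]


def prepare_hog_window(img: RGBImage) -> GrayWindow:
    """Grayscale, center-crop to 200x100 and bilinearly resize to 128x64.

    Images smaller than the crop in either dimension are first scaled up
    (bilinear) just enough for the crop to fit, so any valid input yields a
    window of the fixed shape.
    """
    gray = _to_gray(img)
    ch, cw = HOG_CROP_SHAPE
    h, w = gray.shape
    if h < ch or w < cw:
        scale = max(ch / h, cw / w)
        new_shape = (max(ch, int(np.ceil(h * scale))), max(cw, int(np.ceil(w * scale))))
        gray = _sk_resize(
            gray, new_shape, order=1, anti_aliasing=False, preserve_range=True
        )
    cropped = _center_crop(gray, HOG_CROP_SHAPE)
    win = _sk_resize(
        cropped, HOG_WINDOW_SHAPE, order=1, anti_aliasing=False, preserve_range=True
    )
    return GrayWindow(grid=win)
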