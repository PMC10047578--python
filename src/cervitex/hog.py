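"""Histogram-of-oriented-gradients descriptor and PCA reduction to 20 components.

The descriptor follows the classic pedestrian-detection geometry: a 64-wide
by 128-tall grayscale window, 8x8-pixel cells, 9 unsigned orientation bins
over [0, 180), magnitude-weighted votes linearly interpolated between the
two nearest bin centres, and 2x2-cell blocks at stride one cell with L2-Hys
normalization.  That geometry yields a raw descriptor of length
(16-1) x (8-1) x 4 x 9 = 3780, which PCA reduces to a 20-vector per image.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA

from .exceptions import ModelMismatchError, RankError, ShapeError
from .image_prep import GrayWindow, HOG_WINDOW_SHAPE, RGBImage, prepare_hog_window

__all__ = [
    "HogConfig",
    "GradientField",
    "PcaModel",
    "gradient_field",
    "hog_cell_histograms",
    "hog_descriptor",
    "fit_pca",
    "hog_per_image",
    "raw_descriptor_length",
]


@dataclass(frozen=True)
class HogConfig:
    """Descriptor geometry; defaults give a 3780-long raw vector on 128x64."""

    cell: int = 8
    bins: int = 9
    block: int = 2  # cells per block side, stride 1 cell
    clip: float = 0.2  # L2-Hys clipping threshold
    eps: float = 1e-10


@dataclass
class GradientField:
    """Per-pixel derivatives, magnitude and unsigned orientation (degrees)."""

    gx: np.ndarray
    gy: np.ndarray
    g: np.ndarray
    theta: np.ndarray


@dataclass
class PcaModel:
    """Orthonormal loadings, training mean, and non-increasing explained variance."""

    components: np.ndarray  # (k, D)
    mean: np.ndarray  # (D,)
    explained_variance: np.ndarray  # (k,)

    @property
    def n_components(self) -> int:
        return self.components.shape[0]

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=np.float64))
        if X.shape[1] != self.mean.shape[0]:
            raise ModelMismatchError(
                f"model expects vectors of length {self.mean.shape[0]}, "
                f"got {X.shape[1]}"
            )
        return (X - self.mean) @ self.components.T

    def inverse_transform(self, Z: np.ndarray) -> np.ndarray:
        Z = np.atleast_2d(np.asarray(Z, dtype=np.float64))
        return Z @ self.components + self.mean


def gradient_field(w: GrayWindow | np.ndarray) -> GradientField:
    """Central differences (one-sided at borders), magnitude and orientation.

    Orientation is the two-argument arctangent of (gy, gx) folded to
    [0, 180) degrees (unsigned gradients).
    """
    grid = w.grid if isinstance(w, GrayWindow) else np.asarray(w, dtype=np.float64)
    gy, gx = np.gradient(grid)
    g = np.hypot(gx, gy)
    theta = np.degrees(np.arctan2(gy, gx)) % 180.0
    return GradientField(gx=gx, gy=gy, g=g, theta=theta)


def hog_cell_histograms(
    w: GrayWindow | np.ndarray, config: HogConfig = HogConfig()
) -> np.ndarray:
    """Magnitude-weighted orientation histograms per cell, shape (rows, cols, bins)."""
    grid = w.grid if isinstance(w, GrayWindow) else np.asarray(w, dtype=np.float64)
    c = config.cell
    if grid.shape[0] % c or grid.shape[1] % c:
        raise ShapeError(f"window shape {grid.shape} is not a multiple of cell {c}")
    field = gradient_field(grid)
    nb = config.bins
    bw = 180.0 / nb  # bin width; centres at (b + 0.5) * bw, circular over 180
    pos = field.theta / bw - 0.5
    lo = np.floor(pos).astype(np.int64)
    frac = pos - lo
    lo_bin = lo % nb
    hi_bin = (lo + 1) % nb
    w_lo = field.g * (1.0 - frac)
    w_hi = field.g * frac

    rows, cols = grid.shape[0] // c, grid.shape[1] // c
    cell_r = (np.arange(grid.shape[0]) // c)[:, None]
    cell_c = (np.arange(grid.shape[1]) // c)[None, :]
    cell_idx = np.broadcast_to(cell_r * cols + cell_c, grid.shape).ravel()

    hist = np.zeros((rows * cols, nb))
    np.add.at(hist, (cell_idx, lo_bin.ravel()), w_lo.ravel())
    np.add.at(hist, (cell_idx, hi_bin.ravel()), w_hi.ravel())
    return hist.reshape(rows, cols, nb)


def hog_descriptor(
    w: GrayWindow | np.ndarray, config: HogConfig = HogConfig()
) -> np.ndarray:
    """Raw block-normalized descriptor (length 3780 with the defaults on 128x64)."""
    grid = w.grid if isinstance(w, GrayWindow) else np.asarray(w, dtype=np.float64)
    if isinstance(w, GrayWindow) and grid.shape != HOG_WINDOW_SHAPE:
        raise ShapeError(f"expected window shape {HOG_WINDOW_SHAPE}, got {grid.shape}")
    cells = hog_cell_histograms(grid, config)
    rows, cols, nb = cells.shape
    b = config.block
    if rows < b or cols < b:
        raise ShapeError(f"cell grid {rows}x{cols} smaller than block {b}x{b}")
    blocks = []
    for r in range(rows - b + 1):
        for col in range(cols - b + 1):
            v = cells[r : r + b, col : col + b].ravel()
            v = v / np.sqrt((v**2).sum() + config.eps**2)
            v = np.minimum(v, config.clip)  # L2-Hys: clip then renormalize
            v = v / np.sqrt((v**2).sum() + config.eps**2)
            blocks.append(v)
    return np.concatenate(blocks)


def raw_descriptor_length(
    shape: tuple[int, int] = HOG_WINDOW_SHAPE, config: HogConfig = HogConfig()
) -> int:
    """Closed-form descriptor length for a window shape and config."""
    rows, cols = shape[0] // config.cell, shape[1] // config.cell
    b = config.block
    return (rows - b + 1) * (cols - b + 1) * b * b * config.bins


def fit_pca(descriptors: np.ndarray, k: int = 20) -> PcaModel:
    """Fit mean-centred principal components, deterministic up to fixed signs.

    Signs are fixed so each component's largest-magnitude loading is positive.
    """
    X = np.asarray(descriptors, dtype=np.float64)
    if X.ndim != 2:
        raise ShapeError("descriptors must be a 2-D (samples x features) matrix")
    if X.shape[0] < k:
        raise RankError(
            f"need at least {k} samples to fit {k} components, got {X.shape[0]} "
            f"({k - X.shape[0]} short)"
        )
    pca = PCA(n_components=k, svd_solver="full")
    pca.fit(X)
    comps = pca.components_.copy()
    for row in comps:
        if row[np.argmax(np.abs(row))] < 0:
            row *= -1.0
    return PcaModel(
        components=comps,
        mean=pca.mean_.copy(),
        explained_variance=pca.explained_variance_.copy(),
    )


def hog_per_image(
    img: RGBImage, model: PcaModel, config: HogConfig = HogConfig()
) -> np.ndarray:
    """Window preparation, raw descriptor, and projection onto the components."""
    raw = hog_descriptor(prepare_hog_window(img), config)
    return model.transform(raw[None, :])[0]


def hog_feature_names(k: int = 20) -> list[str]:
    return [f"hog_pc{i + 1:02d}" for i in range(k)]
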