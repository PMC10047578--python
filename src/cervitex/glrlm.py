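"""Gray-level run-length matrices and their texture statistics.

A *run* is a maximal set of consecutive collinear pixels sharing one
quantized gray level.  The run-length matrix ``P`` for a direction theta
counts, in ``P[i, j]``, the runs of gray level ``i`` with length ``j``.
Seven statistics are computed per matrix, averaged over the four scan
directions (0, 45, 90, 135 degrees), and concatenated over the R, G, B
channels: 7 x 3 = 21 features per image.

Feature order per channel: SRE, LRE, GLN, RLN, RP, SRLGLE, LRLGLE.
A long-run high-gray-level emphasis (LRHGLE) can be appended via
``include_lrhgle`` for users wanting the full eight-statistic set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import ConsistencyError, ParameterError
from .image_prep import QuantizedChannel, RGBImage, quantize, split_channels

__all__ = [
    "DIRECTIONS",
    "GLRLM_FEATURE_NAMES",
    "RunLengthMatrix",
    "run_length_matrix",
    "glrlm_feature_vector",
    "glrlm_per_image",
    "glrlm_feature_names",
]

#: Scan directions in degrees: horizontal, anti-diagonal, vertical, diagonal.
DIRECTIONS = (0, 45, 90, 135)

GLRLM_FEATURE_NAMES = ("sre", "lre", "gln", "rln", "rp", "srlgle", "lrlgle")


@dataclass
class RunLengthMatrix:
    """Run counts ``P[i-1, j-1]`` for gray level i, run length j, one direction."""

    P: np.ndarray
    theta: int
    ng: int
    np_pixels: int

    @property
    def nr(self) -> int:
        """Total number of runs."""
        return int(self.P.sum())

    @property
    def lmax(self) -> int:
        return self.P.shape[1]


def _grid_lines(grid: np.ndarray, theta: int) -> list[np.ndarray]:
    """All scan lines of the grid in direction theta.

    45 degrees runs up-right (anti-diagonal), 135 down-right (diagonal).
    """
    if theta == 0:
        return list(grid)
    if theta == 90:
        return list(grid.T)
    h, w = grid.shape
    if theta == 45:
        src = np.flipud(grid)
    elif theta == 135:
        src = grid
    else:
        raise ParameterError(f"theta must be one of {DIRECTIONS}, got {theta}")
    return [src.diagonal(k) for k in range(-h + 1, w)]


def _count_runs(lines: list[np.ndarray], ng: int, lmax: int) -> np.ndarray:
    # Concatenate lines with 0 sentinels so run boundaries never cross lines;
    # levels are >= 1 so sentinel runs are dropped afterwards.
    buf = np.concatenate([np.append(np.asarray(ln, dtype=np.int64), 0) for ln in lines])
    change = np.flatnonzero(np.diff(buf) != 0)
    starts = np.concatenate(([0], change + 1))
    ends = np.concatenate((change, [buf.size - 1]))
    vals = buf[starts]
    lens = ends - starts + 1
    keep = vals > 0
    P = np.zeros((ng, lmax), dtype=np.int64)
    np.add.at(P, (vals[keep] - 1, lens[keep] - 1), 1)
    return P


def run_length_matrix(q: QuantizedChannel, theta: int) -> RunLengthMatrix:
    """Count maximal runs along every line of the grid in direction ``theta``.

    Every pixel belongs to exactly one maximal run per direction, so
    ``sum_{i,j} j * P[i, j]`` equals the pixel count.
    """
    if theta not in DIRECTIONS:
        raise ParameterError(f"theta must be one of {DIRECTIONS}, got {theta}")
    grid = q.grid
    if grid.size == 0:
        raise ParameterError("cannot build a run-length matrix from an empty grid")
    lmax = max(grid.shape)
    P = _count_runs(_grid_lines(grid, theta), q.ng, lmax)
    return RunLengthMatrix(P=P, theta=theta, ng=q.ng, np_pixels=int(grid.size))


def _direction_features(m: RunLengthMatrix, include_lrhgle: bool = False) -> np.ndarray:
    P = m.P.astype(np.float64)
    nr = float(m.nr)
    j2 = np.arange(1, m.lmax + 1, dtype=np.float64) ** 2  # run-length weights
    i2 = np.arange(1, m.ng + 1, dtype=np.float64) ** 2  # gray-level weights
    sre = float((P / j2).sum() / nr)
    lre = float((P * j2).sum() / nr)
    gln = float((P.sum(axis=1) ** 2).sum() / nr)
    rln = float((P.sum(axis=0) ** 2).sum() / nr)
    rp = nr / m.np_pixels
    srlgle = float((P / (i2[:, None] * j2[None, :])).sum() / nr)
    lrlgle = float((P * (j2[None, :] / i2[:, None])).sum() / nr)
    feats = [sre, lre, gln, rln, rp, srlgle, lrlgle]
    if include_lrhgle:
        feats.append(float((P * (i2[:, None] * j2[None, :])).sum() / nr))
    return np.array(feats)


def glrlm_feature_vector(
    mats: list[RunLengthMatrix], include_lrhgle: bool = False
) -> np.ndarray:
    """Per-direction statistics averaged over the four directions.

    ``mats`` must come from the same channel (equal pixel count and ng).
    """
    if len(mats) == 0:
        raise ParameterError("need at least one run-length matrix")
    np_set = {m.np_pixels for m in mats}
    ng_set = {m.ng for m in mats}
    if len(np_set) != 1 or len(ng_set) != 1:
        raise ConsistencyError(
            "run-length matrices disagree on pixel count or gray levels; "
            "they must come from the same channel"
        )
    per_dir = np.stack([_direction_features(m, include_lrhgle) for m in mats])
    return per_dir.mean(axis=0)


def glrlm_per_image(
    img: RGBImage, ng: int = 8, include_lrhgle: bool = False
) -> np.ndarray:
    """7 direction-averaged statistics per channel, concatenated R, G, B (length 21)."""
    blocks = []
    for channel in split_channels(img):
        q = quantize(channel, ng)
        mats = [run_length_matrix(q, theta) for theta in DIRECTIONS]
        blocks.append(glrlm_feature_vector(mats, include_lrhgle))
    return np.concatenate(blocks)


def glrlm_feature_names(include_lrhgle: bool = False) -> list[str]:
    """Column names matching :func:`glrlm_per_image` output order."""
    names = list(GLRLM_FEATURE_NAMES)
    if include_lrhgle:
        names.append("lrhgle")
    return [f"glrlm_{ch}_{n}" for ch in "rgb" for n in names]
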