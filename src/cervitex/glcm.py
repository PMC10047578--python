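"""Gray-level co-occurrence matrices and the 22-statistic Haralick/Soh/Clausi set.

The co-occurrence matrix for an offset (direction theta, distance d) holds
the joint frequency ``p(m, n)`` of a pixel at level m having a neighbour at
level n at that offset.  Matrices are symmetrized (pairs counted in both
orders) and normalized to sum 1, so the marginals satisfy mu_x = mu_y and
Haralick's marginal-based statistics are well defined.

22 statistics are computed per matrix, averaged over the four offsets at
d = 1, and concatenated over the R, G, B channels: 22 x 3 = 66 per image.

Conventions for degenerate inputs: natural logarithms with 0*log(0) := 0;
when a marginal standard deviation vanishes (constant channel) the two
correlation statistics and the information measures of correlation are
defined as 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import ConsistencyError, DegenerateInputError, ParameterError
from .image_prep import QuantizedChannel, RGBImage, quantize, split_channels

__all__ = [
    "DIRECTIONS",
    "GLCM_FEATURE_NAMES",
    "CoocMatrix",
    "cooccurrence_matrix",
    "glcm_feature_vector",
    "glcm_per_image",
    "glcm_feature_names",
]

DIRECTIONS = (0, 45, 90, 135)

#: (row, col) step per unit distance for each direction; sign is immaterial
#: after symmetrization.
_OFFSETS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}

GLCM_FEATURE_NAMES = (
    "autocorrelation",
    "contrast",
    "correlation1",
    "correlation2",
    "cluster_prominence",
    "cluster_shade",
    "dissimilarity",
    "energy",
    "entropy",
    "homogeneity1",
    "homogeneity2",
    "max_probability",
    "sum_of_squares_variance",
    "sum_average",
    "sum_variance",
    "sum_entropy",
    "difference_variance",
    "difference_entropy",
    "imc1",
    "imc2",
    "inverse_difference_normalized",
    "inverse_difference_moment_normalized",
)


@dataclass
class CoocMatrix:
    """Normalized symmetric pair-frequency matrix for one offset."""

    p: np.ndarray
    theta: int
    d: int
    ng: int

    @property
    def mu_x(self) -> float:
        i = np.arange(1, self.ng + 1)
        return float((i * self.p.sum(axis=1)).sum())

    @property
    def mu_y(self) -> float:
        j = np.arange(1, self.ng + 1)
        return float((j * self.p.sum(axis=0)).sum())

    @property
    def sigma_x(self) -> float:
        i = np.arange(1, self.ng + 1)
        px = self.p.sum(axis=1)
        return float(np.sqrt(((i - self.mu_x) ** 2 * px).sum()))

    @property
    def sigma_y(self) -> float:
        j = np.arange(1, self.ng + 1)
        py = self.p.sum(axis=0)
        return float(np.sqrt(((j - self.mu_y) ** 2 * py).sum()))


def cooccurrence_matrix(q: QuantizedChannel, theta: int, d: int = 1) -> CoocMatrix:
    """Count ordered pixel pairs at the offset, symmetrize, normalize to sum 1."""
    if theta not in DIRECTIONS:
        raise ParameterError(f"theta must be one of {DIRECTIONS}, got {theta}")
    if d < 1:
        raise ParameterError(f"distance must be >= 1, got {d}")
    grid = q.grid
    dr, dc = _OFFSETS[theta]
    dr, dc = dr * d, dc * d
    h, w = grid.shape
    r0, r1 = max(0, -dr), min(h, h - dr)
    c0, c1 = max(0, -dc), min(w, w - dc)
    if r0 >= r1 or c0 >= c1:
        raise DegenerateInputError(
            f"no pixel pair fits offset theta={theta}, d={d} in a {h}x{w} grid"
        )
    a = grid[r0:r1, c0:c1].ravel()
    b = grid[r0 + dr : r1 + dr, c0 + dc : c1 + dc].ravel()
    counts = np.zeros((q.ng, q.ng), dtype=np.int64)
    np.add.at(counts, (a - 1, b - 1), 1)
    counts = counts + counts.T
    p = counts / counts.sum()
    return CoocMatrix(p=p, theta=theta, d=d, ng=q.ng)


def _xlogx(x: np.ndarray) -> np.ndarray:
    out = np.zeros_like(x)
    nz = x > 0
    out[nz] = x[nz] * np.log(x[nz])
    return out


def _direction_features(m: CoocMatrix) -> np.ndarray:
    p = m.p
    if not np.isclose(p.sum(), 1.0, atol=1e-9):
        raise ConsistencyError("co-occurrence matrix is not normalized to sum 1")
    ng = m.ng
    lev = np.arange(1, ng + 1, dtype=np.float64)
    ii, jj = np.meshgrid(lev, lev, indexing="ij")
    px, py = p.sum(axis=1), p.sum(axis=0)
    mux, muy = m.mu_x, m.mu_y
    sx, sy = m.sigma_x, m.sigma_y

    autoc = float((ii * jj * p).sum())
    contrast = float(((ii - jj) ** 2 * p).sum())
    if sx * sy > 0:
        corr1 = float((((ii - mux) * (jj - muy) * p).sum()) / (sx * sy))
        corr2 = float((autoc - mux * muy) / (sx * sy))
    else:
        corr1 = corr2 = 0.0
    cprom = float(((ii + jj - mux - muy) ** 4 * p).sum())
    cshade = float(((ii + jj - mux - muy) ** 3 * p).sum())
    dissim = float((np.abs(ii - jj) * p).sum())
    energy = float((p**2).sum())
    entropy = float(-_xlogx(p).sum())
    homog1 = float((p / (1.0 + np.abs(ii - jj))).sum())
    homog2 = float((p / (1.0 + (ii - jj) ** 2)).sum())
    maxprob = float(p.max())
    sosvar = float(((ii - mux) ** 2 * p).sum())

    # sum and difference distributions over k = i + j and k = |i - j|
    ksum = (ii + jj).astype(np.int64).ravel()
    pxy_sum = np.bincount(ksum, weights=p.ravel(), minlength=2 * ng + 1)[2:]
    ks = np.arange(2, 2 * ng + 1, dtype=np.float64)
    savg = float((ks * pxy_sum).sum())
    svar = float(((ks - savg) ** 2 * pxy_sum).sum())
    sent = float(-_xlogx(pxy_sum).sum())

    kdiff = np.abs(ii - jj).astype(np.int64).ravel()
    pxy_diff = np.bincount(kdiff, weights=p.ravel(), minlength=ng)[:ng]
    kd = np.arange(ng, dtype=np.float64)
    davg = float((kd * pxy_diff).sum())
    dvar = float(((kd - davg) ** 2 * pxy_diff).sum())
    dent = float(-_xlogx(pxy_diff).sum())

    hx = float(-_xlogx(px).sum())
    hy = float(-_xlogx(py).sum())
    pxpy = np.outer(px, py)
    mask = (p > 0) & (pxpy > 0)
    hxy1 = float(-(p[mask] * np.log(pxpy[mask])).sum())
    hxy2 = float(-_xlogx(pxpy).sum())
    denom = max(hx, hy)
    imc1 = float((entropy - hxy1) / denom) if denom > 0 else 0.0
    imc2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - entropy)))))

    idn = float((p / (1.0 + np.abs(ii - jj) / ng)).sum())
    idmn = float((p / (1.0 + (ii - jj) ** 2 / ng**2)).sum())

    return np.array(
        [
            autoc,
            contrast,
            corr1,
            corr2,
            cprom,
            cshade,
            dissim,
            energy,
            entropy,
            homog1,
            homog2,
            maxprob,
            sosvar,
            savg,
            svar,
            sent,
            dvar,
            dent,
            imc1,
            imc2,
            idn,
            idmn,
        ]
    )


def glcm_feature_vector(mats: list[CoocMatrix]) -> np.ndarray:
    """22 statistics per matrix, averaged over the four offsets."""
    if len(mats) == 0:
        raise ParameterError("need at least one co-occurrence matrix")
    if len({m.ng for m in mats}) != 1:
        raise ConsistencyError("co-occurrence matrices disagree on gray levels")
    return np.stack([_direction_features(m) for m in mats]).mean(axis=0)


def glcm_per_image(img: RGBImage, ng: int = 8, d: int = 1) -> np.ndarray:
    """22 direction-averaged statistics per channel, concatenated R, G, B (length 66)."""
    blocks = []
    for channel in split_channels(img):
        q = quantize(channel, ng)
        mats = [cooccurrence_matrix(q, theta, d) for theta in DIRECTIONS]
        blocks.append(glcm_feature_vector(mats))
    return np.concatenate(blocks)


def glcm_feature_names() -> list[str]:
    """Column names matching :func:`glcm_per_image` output order."""
    return [f"glcm_{ch}_{n}" for ch in "rgb" for n in GLCM_FEATURE_NAMES]
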