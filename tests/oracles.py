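"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written for clarity, not speed: plain Python loops that
enumerate runs and pixel pairs directly from the definitions.  These
routines deliberately share no code with the package.
"""

from __future__ import annotations

import math

import numpy as np

_STEPS = {0: (0, 1), 45: (-1, 1), 90: (1, 0), 135: (1, 1)}


def _line_starts(h, w, dr, dc):
    """Starting pixels of every scan line for a step (dr, dc)."""
    starts = []
    for r in range(h):
        for c in range(w):
            pr, pc = r - dr, c - dc
            if not (0 <= pr < h and 0 <= pc < w):
                starts.append((r, c))
    return starts


def runs_brute(grid, theta):
    """Enumerate every maximal run: list of (level, length) tuples."""
    grid = np.asarray(grid)
    h, w = grid.shape
    dr, dc = _STEPS[theta]
    runs = []
    for r0, c0 in _line_starts(h, w, dr, dc):
        line = []
        r, c = r0, c0
        while 0 <= r < h and 0 <= c < w:
            line.append(int(grid[r, c]))
            r, c = r + dr, c + dc
        i = 0
        while i < len(line):
            j = i
            while j < len(line) and line[j] == line[i]:
                j += 1
            runs.append((line[i], j - i))
            i = j
    return runs


def rlm_brute(grid, theta, ng):
    """Run-length count matrix (ng x max(h, w)) from the enumerated runs."""
    grid = np.asarray(grid)
    P = np.zeros((ng, max(grid.shape)), dtype=np.int64)
    for level, length in runs_brute(grid, theta):
        P[level - 1, length - 1] += 1
    return P


def glrlm_features_brute(grid, theta, ng):
    """Term-by-term evaluation of the seven run-length statistics."""
    P = rlm_brute(grid, theta, ng)
    nr = P.sum()
    npx = np.asarray(grid).size
    sre = lre = gln = rln = srlgle = lrlgle = 0.0
    for i in range(1, ng + 1):
        for j in range(1, P.shape[1] + 1):
            c = P[i - 1, j - 1]
            sre += c / j**2
            lre += c * j**2
            srlgle += c / (i**2 * j**2)
            lrlgle += c * j**2 / i**2
    for i in range(1, ng + 1):
        gln += P[i - 1].sum() ** 2
    for j in range(1, P.shape[1] + 1):
        rln += P[:, j - 1].sum() ** 2
    return {
        "sre": sre / nr,
        "lre": lre / nr,
        "gln": gln / nr,
        "rln": rln / nr,
        "rp": nr / npx,
        "srlgle": srlgle / nr,
        "lrlgle": lrlgle / nr,
    }


_OFFSETS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}


def cooc_brute(grid, theta, d, ng):
    """Symmetrized, normalized co-occurrence matrix by full pair enumeration."""
    grid = np.asarray(grid)
    h, w = grid.shape
    dr, dc = _OFFSETS[theta]
    dr, dc = dr * d, dc * d
    C = np.zeros((ng, ng), dtype=np.int64)
    for r in range(h):
        for c in range(w):
            r2, c2 = r + dr, c + dc
            if 0 <= r2 < h and 0 <= c2 < w:
                C[grid[r, c] - 1, grid[r2, c2] - 1] += 1
                C[grid[r2, c2] - 1, grid[r, c] - 1] += 1
    return C / C.sum()


def glcm_printed_stats_brute(grid, theta, d, ng):
    """The six textbook co-occurrence statistics, summed cell by cell."""
    p = cooc_brute(grid, theta, d, ng)
    maxprob = p.max()
    contrast = energy = entropy = homog = dissim = 0.0
    mux = muy = 0.0
    for i in range(1, ng + 1):
        for j in range(1, ng + 1):
            mux += i * p[i - 1, j - 1]
            muy += j * p[i - 1, j - 1]
    sx = sy = 0.0
    for i in range(1, ng + 1):
        for j in range(1, ng + 1):
            sx += (i - mux) ** 2 * p[i - 1, j - 1]
            sy += (j - muy) ** 2 * p[i - 1, j - 1]
    sx, sy = math.sqrt(sx), math.sqrt(sy)
    corr_num = 0.0
    for i in range(1, ng + 1):
        for j in range(1, ng + 1):
            v = p[i - 1, j - 1]
            contrast += (i - j) ** 2 * v
            energy += v * v
            if v > 0:
                entropy -= v * math.log(v)
            homog += v / (1 + abs(i - j))
            dissim += abs(i - j) * v
            corr_num += v * (i * j - mux * muy)
    correlation = corr_num / (sx * sy) if sx * sy > 0 else 0.0
    return {
        "max_probability": maxprob,
        "correlation2": correlation,
        "contrast": contrast,
        "energy": energy,
        "homogeneity1": homog,
        "dissimilarity": dissim,
        "entropy": entropy,
    }


def pca_eig_oracle(X, k):
    """Principal components via eigendecomposition of the sample covariance."""
    X = np.asarray(X, dtype=np.float64)
    mean = X.mean(axis=0)
    cov = np.cov(X - mean, rowvar=False)
    vals, vecs = np.linalg.eigh(cov)
    order = np.argsort(vals)[::-1][:k]
    return mean, vals[order], vecs[:, order].T


def bilinear_sample(img, r, c):
    """Bilinear interpolation of a 2-D array at fractional (row, col)."""
    img = np.asarray(img, dtype=np.float64)
    r0, c0 = int(np.floor(r)), int(np.floor(c))
    r1 = min(r0 + 1, img.shape[0] - 1)
    c1 = min(c0 + 1, img.shape[1] - 1)
    fr, fc = r - r0, c - c0
    return (
        img[r0, c0] * (1 - fr) * (1 - fc)
        + img[r1, c0] * fr * (1 - fc)
        + img[r0, c1] * (1 - fr) * fc
        + img[r1, c1] * fr * fc
    )
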