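"""Fusion of the three per-image feature blocks into the 107-vector.

Layout: GLRLM occupies indices 0-20, GLCM 21-86, HOG 87-106.  No feature
scaling is applied before fusion; classifiers that require standardization
do it internally on their training folds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .exceptions import EmptyDatasetError, LayoutError, ParameterError
from .glcm import glcm_feature_names, glcm_per_image
from .glrlm import glrlm_feature_names, glrlm_per_image
from .hog import (
    HogConfig,
    PcaModel,
    fit_pca,
    hog_descriptor,
    hog_feature_names,
    hog_per_image,
)
from .image_prep import RGBImage, prepare_hog_window

__all__ = [
    "BLOCK_WIDTHS",
    "FUSED_LENGTH",
    "FusedVector",
    "FeatureTables",
    "fuse",
    "fused_feature_names",
    "extract_features",
    "build_feature_table",
]

BLOCK_WIDTHS = {"glrlm": 21, "glcm": 66, "hog": 20}
FUSED_LENGTH = sum(BLOCK_WIDTHS.values())

_SLICES = {
    "glrlm": slice(0, 21),
    "glcm": slice(21, 87),
    "hog": slice(87, 107),
}


@dataclass
class FusedVector:
    """The ordered 107-vector with its layout and provenance."""

    values: np.ndarray
    source_id: str = ""
    label: Optional[str] = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        if v.shape != (FUSED_LENGTH,):
            raise LayoutError(f"fused vector must have length {FUSED_LENGTH}")
        if not np.all(np.isfinite(v)):
            raise LayoutError("fused vector entries must be finite")
        self.values = v

    def block(self, name: str) -> np.ndarray:
        return self.values[_SLICES[name]]


def fuse(glrlm: np.ndarray, glcm: np.ndarray, hog: np.ndarray, **kw) -> FusedVector:
    """Concatenate the three blocks in order GLRLM | GLCM | HOG."""
    for name, vec in (("glrlm", glrlm), ("glcm", glcm), ("hog", hog)):
        vec = np.asarray(vec)
        if vec.shape != (BLOCK_WIDTHS[name],):
            raise LayoutError(
                f"{name} block must have length {BLOCK_WIDTHS[name]}, "
                f"got shape {vec.shape}"
            )
    return FusedVector(values=np.concatenate([glrlm, glcm, hog]), **kw)


def fused_feature_names() -> list[str]:
    return glrlm_feature_names() + glcm_feature_names() + hog_feature_names()


@dataclass
class FeatureTables:
    """Per-image feature blocks for a dataset, with raw HOG kept for fold-wise PCA.

    ``hog_raw`` holds the un-reduced block-normalized descriptors so that a
    PCA can be fitted on each cross-validation training split without leaking
    test information; a dataset-level fit is available via :meth:`hog_pca`.
    """

    ids: list[str]
    labels: np.ndarray  # array of "normal"/"abnormal" strings
    glrlm: np.ndarray  # (n, 21)
    glcm: np.ndarray  # (n, 66)
    hog_raw: np.ndarray  # (n, raw descriptor length)
    failures: list[tuple[str, str]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.ids)

    def hog_pca(self, k: int = 20) -> PcaModel:
        """PCA fitted on all rows (the dataset-level, publication-style fit)."""
        return fit_pca(self.hog_raw, k=k)


def extract_features(
    dataset: Sequence[RGBImage],
    ng: int = 8,
    d: int = 1,
    hog_config: HogConfig = HogConfig(),
) -> FeatureTables:
    """Extract GLRLM, GLCM and raw HOG blocks for every image.

    A failing image is skipped and reported in ``failures`` as
    ``(source_id, message)``; the run continues.
    """
    dataset = list(dataset)
    if not dataset:
        raise EmptyDatasetError("cannot extract features from an empty dataset")
    ids, labels, g1, g2, hraw, failures = [], [], [], [], [], []
    for img in dataset:
        try:
            g1.append(glrlm_per_image(img, ng))
            g2.append(glcm_per_image(img, ng, d))
            hraw.append(hog_descriptor(prepare_hog_window(img), hog_config))
        except Exception as exc:  # noqa: BLE001 - row-level isolation by contract
            failures.append((img.source_id, str(exc)))
            continue
        ids.append(img.source_id)
        labels.append(img.label)
    if not ids:
        raise EmptyDatasetError("feature extraction failed for every image")
    return FeatureTables(
        ids=ids,
        labels=np.asarray(labels, dtype=object),
        glrlm=np.vstack(g1),
        glcm=np.vstack(g2),
        hog_raw=np.vstack(hraw),
        failures=failures,
    )


def build_feature_table(
    dataset: Sequence[RGBImage],
    block: str = "hybrid",
    ng: int = 8,
    d: int = 1,
    k: int = 20,
    pca_model: Optional[PcaModel] = None,
) -> pd.DataFrame:
    """One row per image: source_id, label, and the named feature columns.

    ``block`` selects ``hybrid`` (107 columns) or a single block.  When the
    HOG block is requested and no fitted ``pca_model`` is passed, a PCA is
    fitted on this dataset's own descriptors (requires at least ``k`` images).
    """
    if block not in ("hybrid", "glrlm", "glcm", "hog"):
        raise ParameterError(f"unknown block {block!r}")
    tables = extract_features(dataset, ng=ng, d=d)
    cols: dict[str, np.ndarray] = {}
    if block in ("hybrid", "glrlm"):
        for name, col in zip(glrlm_feature_names(), tables.glrlm.T):
            cols[name] = col
    if block in ("hybrid", "glcm"):
        for name, col in zip(glcm_feature_names(), tables.glcm.T):
            cols[name] = col
    if block in ("hybrid", "hog"):
        model = pca_model if pca_model is not None else tables.hog_pca(k)
        hog20 = model.transform(tables.hog_raw)
        for name, col in zip(hog_feature_names(model.n_components), hog20.T):
            cols[name] = col
    frame = pd.DataFrame(cols)
    frame.insert(0, "label", tables.labels)
    frame.insert(0, "source_id", tables.ids)
    frame.attrs["failures"] = tables.failures
    return frame
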