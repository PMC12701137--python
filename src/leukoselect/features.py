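"""Descriptor feature bank.

Turns labelled single-cell crops into the samples x features matrix that the
wrapper selectors operate on. The default path is a deterministic descriptor
bank over three families:

- ``color``: per-channel mean / SD / skewness / excess kurtosis of the cell
  region in RGB and HSV (24 values) plus nucleus-region channel means (6);
- ``texture``: grey-level co-occurrence contrast, correlation, energy and
  homogeneity averaged over a set of pixel offsets, computed on the
  quantized cell region only;
- ``shape``: cell area, perimeter, circularity 4*pi*A/P^2, solidity,
  nucleus/cell area ratio and nucleus circularity.

Conventions: population (divide-by-n) moments throughout; skewness, kurtosis
and GLCM correlation of a zero-variance region are 0 by definition; GLCM
"energy" is the angular second moment sum(P^2).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import binary_fill_holes
from skimage.color import rgb2gray, rgb2hsv
from skimage.measure import label as cc_label
from skimage.measure import perimeter as mask_perimeter
from skimage.morphology import convex_hull_image
from sklearn.base import BaseEstimator, TransformerMixin

from .errors import (
    EmptyRegionError,
    ExtractionError,
    SegmentationDegenerateError,
    TextureDegenerateError,
)
from .synthetic import DatasetManifest, ImageSample, load_samples

__all__ = [
    "CellMask",
    "ExtractorSpec",
    "FeatureMatrix",
    "segment_cell",
    "color_features",
    "texture_features",
    "shape_features",
    "extract_sample",
    "extract_features",
    "assemble_matrix",
    "standardize_matrix",
    "DescriptorExtractor",
]

FAMILY_ORDER = ("color", "texture", "shape")


@dataclass(frozen=True)
class CellMask:
    """Cell and nucleus boolean masks; the nucleus is a subset of the cell."""

    mask: np.ndarray
    nucleus_mask: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.mask, dtype=bool)
        n = np.asarray(self.nucleus_mask, dtype=bool)
        if m.shape != n.shape or m.ndim != 2:
            raise ValueError("mask and nucleus_mask must be 2-D arrays of equal shape")
        if np.any(n & ~m):
            raise ValueError("nucleus_mask must be a subset of mask")
        object.__setattr__(self, "mask", m)
        object.__setattr__(self, "nucleus_mask", n)


@dataclass(frozen=True)
class ExtractorSpec:
    """Which descriptor families to compute and how."""

    families: tuple[str, ...] = FAMILY_ORDER
    glcm_levels: int = 8
    glcm_offsets: tuple[tuple[int, int], ...] = ((0, 1), (1, 0))
    standardize: str = "train_only"

    def __post_init__(self) -> None:
        fams = tuple(self.families)
        if not fams:
            raise ValueError("at least one feature family must be enabled")
        unknown = set(fams) - set(FAMILY_ORDER)
        if unknown:
            raise ValueError(f"unknown feature families: {sorted(unknown)}")
        object.__setattr__(self, "families", tuple(f for f in FAMILY_ORDER if f in fams))
        if self.glcm_levels < 2:
            raise ValueError("glcm_levels must be >= 2")
        if self.standardize not in ("none", "train_only", "pooled"):
            raise ValueError("standardize must be one of none/train_only/pooled")
        object.__setattr__(self, "glcm_offsets", tuple(tuple(int(v) for v in o) for o in self.glcm_offsets))


@dataclass
class FeatureMatrix:
    """Samples x named features with a label vector; the selection substrate."""

    values: np.ndarray
    feature_names: list[str]
    labels: np.ndarray
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D")
        n, d = self.values.shape
        if len(self.feature_names) != d:
            raise ValueError("feature_names length must match the number of columns")
        if len(set(self.feature_names)) != d:
            raise ValueError("feature_names must be unique")
        if len(self.labels) != n or len(self.sample_ids) != n:
            raise ValueError("labels and sample_ids must match the number of rows")
        if n and not np.all(np.isfinite(self.values)):
            raise ValueError("feature matrix contains non-finite entries")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def select_rows(self, indices: Sequence[int]) -> "FeatureMatrix":
        idx = np.asarray(indices, dtype=int)
        return FeatureMatrix(
            self.values[idx],
            list(self.feature_names),
            self.labels[idx],
            [self.sample_ids[i] for i in idx],
        )

    def select_columns(self, mask: Sequence[int] | np.ndarray) -> "FeatureMatrix":
        m = np.asarray(mask).astype(bool)
        return FeatureMatrix(
            self.values[:, m],
            [n for n, keep in zip(self.feature_names, m) if keep],
            self.labels,
            list(self.sample_ids),
        )

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.feature_names)
        df.insert(0, "label", self.labels)
        df.insert(0, "sample_id", self.sample_ids)
        return df

    def to_csv(self, path: str | Path) -> None:
        # 17 significant digits: lossless float64 round-trip
        self.to_dataframe().to_csv(path, index=False, float_format="%.17g")

    @classmethod
    def from_csv(cls, path: str | Path) -> "FeatureMatrix":
        df = pd.read_csv(path, float_precision="round_trip")
        if "sample_id" not in df.columns or "label" not in df.columns:
            raise ValueError("feature CSV must start with sample_id,label columns")
        names = [c for c in df.columns if c not in ("sample_id", "label")]
        return cls(
            df[names].to_numpy(dtype=np.float64),
            names,
            df["label"].to_numpy(dtype=int),
            df["sample_id"].astype(str).tolist(),
        )


# ---------------------------------------------------------------------------
# segmentation


def _largest_component(binary: np.ndarray) -> np.ndarray:
    labelled, n = cc_label(binary, return_num=True)
    if n == 0:
        return np.zeros_like(binary, dtype=bool)
    counts = np.bincount(labelled.ravel())[1:]
    return labelled == (int(np.argmax(counts)) + 1)


def segment_cell(image: ImageSample | np.ndarray) -> CellMask:
    """Otsu-based two-stage segmentation.

    The cell is the largest connected component of the Otsu-thresholded
    inverse luminance; the nucleus is an Otsu re-threshold restricted to the
    cell region. Both masks are hole-filled. A zero-variance image (Otsu
    undefined) raises :class:`SegmentationDegenerateError`.
    """
    from skimage.filters import threshold_otsu

    pixels = image.pixels if isinstance(image, ImageSample) else np.asarray(image, dtype=np.float64)
    inv = 1.0 - rgb2gray(pixels)
    if np.ptp(inv) < 1e-12:
        raise SegmentationDegenerateError("image has zero variance; Otsu threshold undefined")
    cell = _largest_component(inv > threshold_otsu(inv))
    if not cell.any():
        raise SegmentationDegenerateError("no foreground component above the Otsu threshold")
    cell = binary_fill_holes(cell)

    cell_values = inv[cell]
    if np.ptp(cell_values) < 1e-12:
        nucleus = np.zeros_like(cell)
    else:
        nucleus = (inv > threshold_otsu(cell_values)) & cell
        if nucleus.any():
            nucleus = binary_fill_holes(_largest_component(nucleus)) & cell
    return CellMask(mask=cell, nucleus_mask=nucleus)


# ---------------------------------------------------------------------------
# descriptors


def _moments(x: np.ndarray) -> tuple[float, float, float, float]:
    """Population mean, SD, skewness and excess kurtosis; the latter two are 0 for constants."""
    m = float(x.mean())
    sd = float(np.sqrt(np.mean((x - m) ** 2)))
    if sd < 1e-12:
        return m, sd, 0.0, 0.0
    z = (x - m) / sd
    return m, sd, float(np.mean(z**3)), float(np.mean(z**4) - 3.0)


_STATS = ("mean", "sd", "skew", "kurt")


def color_features(image: ImageSample | np.ndarray, mask: CellMask) -> "pd.Series":
    """30 colour descriptors: RGB and HSV cell-region moments + nucleus channel means."""
    pixels = image.pixels if isinstance(image, ImageSample) else np.asarray(image, dtype=np.float64)
    if not mask.mask.any():
        raise EmptyRegionError("cell mask is empty")
    spaces = {"rgb": pixels, "hsv": rgb2hsv(pixels)}
    channel_names = {"rgb": ("r", "g", "b"), "hsv": ("h", "s", "v")}
    names: list[str] = []
    values: list[float] = []
    for space in ("rgb", "hsv"):
        arr = spaces[space]
        for c, ch in enumerate(channel_names[space]):
            stats = _moments(arr[mask.mask, c])
            for stat, v in zip(_STATS, stats):
                names.append(f"color_{space}_{ch}_{stat}")
                values.append(v)
    for space in ("rgb", "hsv"):
        arr = spaces[space]
        for c, ch in enumerate(channel_names[space]):
            v = float(arr[mask.nucleus_mask, c].mean()) if mask.nucleus_mask.any() else 0.0
            names.append(f"color_nucleus_{space}_{ch}_mean")
            values.append(v)
    return pd.Series(values, index=names, dtype=np.float64)


def _glcm(quantized: np.ndarray, mask: np.ndarray, offset: tuple[int, int], levels: int) -> np.ndarray | None:
    """Symmetric normalized co-occurrence matrix over in-mask pixel pairs, or None if no pairs."""
    dr, dc = offset
    h, w = mask.shape
    r0 = slice(max(0, -dr), min(h, h - dr))
    c0 = slice(max(0, -dc), min(w, w - dc))
    r1 = slice(max(0, dr), min(h, h + dr))
    c1 = slice(max(0, dc), min(w, w + dc))
    pair_mask = mask[r0, c0] & mask[r1, c1]
    if not pair_mask.any():
        return None
    i = quantized[r0, c0][pair_mask]
    j = quantized[r1, c1][pair_mask]
    counts = np.zeros((levels, levels), dtype=np.float64)
    np.add.at(counts, (i, j), 1.0)
    counts = counts + counts.T
    return counts / counts.sum()


def _glcm_props(P: np.ndarray) -> dict[str, float]:
    levels = P.shape[0]
    i, j = np.meshgrid(np.arange(levels), np.arange(levels), indexing="ij")
    contrast = float(np.sum(P * (i - j) ** 2))
    energy = float(np.sum(P**2))
    homogeneity = float(np.sum(P / (1.0 + (i - j) ** 2)))
    pi = P.sum(axis=1)
    mu = float(np.sum(np.arange(levels) * pi))
    var = float(np.sum((np.arange(levels) - mu) ** 2 * pi))
    if var < 1e-12:
        correlation = 0.0  # zero-variance convention
    else:
        correlation = float(np.sum((i - mu) * (j - mu) * P) / var)
    return {"contrast": contrast, "correlation": correlation, "energy": energy, "homogeneity": homogeneity}


def texture_features(
    image: ImageSample | np.ndarray, mask: CellMask, spec: ExtractorSpec | None = None
) -> "pd.Series":
    """GLCM contrast/correlation/energy/homogeneity averaged over the spec's offsets."""
    spec = spec or ExtractorSpec()
    pixels = image.pixels if isinstance(image, ImageSample) else np.asarray(image, dtype=np.float64)
    if not mask.mask.any():
        raise EmptyRegionError("cell mask is empty")
    gray = rgb2gray(pixels)
    region = gray[mask.mask]
    lo, hi = float(region.min()), float(region.max())
    quantized = np.zeros_like(gray, dtype=np.intp)
    if hi - lo > 1e-12:
        q = np.floor((gray - lo) / (hi - lo) * spec.glcm_levels).astype(np.intp)
        quantized = np.clip(q, 0, spec.glcm_levels - 1)

    props_per_offset = []
    for offset in spec.glcm_offsets:
        P = _glcm(quantized, mask.mask, offset, spec.glcm_levels)
        if P is not None:
            props_per_offset.append(_glcm_props(P))
    if not props_per_offset:
        raise TextureDegenerateError("every co-occurrence offset was dropped (region too small)")
    names = ("contrast", "correlation", "energy", "homogeneity")
    values = [float(np.mean([p[k] for p in props_per_offset])) for k in names]
    return pd.Series(values, index=[f"texture_glcm_{k}" for k in names], dtype=np.float64)


def _circularity(area: float, perim: float) -> float:
    return 4.0 * np.pi * area / perim**2 if perim > 0 else 0.0


def shape_features(mask: CellMask) -> "pd.Series":
    """Six shape descriptors of the cell and nucleus masks."""
    if not mask.mask.any():
        raise EmptyRegionError("cell mask is empty")
    area = float(mask.mask.sum())
    perim = float(mask_perimeter(mask.mask))
    hull_area = float(convex_hull_image(mask.mask).sum())
    solidity = area / hull_area if hull_area > 0 else 0.0
    if mask.nucleus_mask.any():
        n_area = float(mask.nucleus_mask.sum())
        n_circ = _circularity(n_area, float(mask_perimeter(mask.nucleus_mask)))
    else:
        warnings.warn("empty nucleus mask: nucleus shape features set to 0", stacklevel=2)
        n_area, n_circ = 0.0, 0.0
    values = [area, perim, _circularity(area, perim), solidity, n_area / area, n_circ]
    names = [
        "shape_cell_area",
        "shape_cell_perimeter",
        "shape_cell_circularity",
        "shape_cell_solidity",
        "shape_nucleus_area_ratio",
        "shape_nucleus_circularity",
    ]
    return pd.Series(values, index=names, dtype=np.float64)


def extract_sample(sample: ImageSample, spec: ExtractorSpec) -> "pd.Series":
    """All enabled descriptor families for one sample, families in declared order."""
    mask = segment_cell(sample)
    parts = []
    for family in spec.families:
        if family == "color":
            parts.append(color_features(sample, mask))
        elif family == "texture":
            parts.append(texture_features(sample, mask, spec))
        elif family == "shape":
            parts.append(shape_features(mask))
    return pd.concat(parts)


# ---------------------------------------------------------------------------
# assembly


def extract_features(
    samples: Iterable[ImageSample],
    spec: ExtractorSpec | None = None,
    train_indices: Sequence[int] | None = None,
) -> FeatureMatrix:
    """Extract descriptors for a sequence of samples and optionally standardize.

    ``pooled`` standardization uses statistics over all rows (the pooled
    train+test convention some pipelines use, which leaks test information
    into scaling); ``train_only`` uses statistics of ``train_indices`` only
    and is deferred (raw matrix returned) when no indices are given.
    """
    spec = spec or ExtractorSpec()
    rows, labels, ids = [], [], []
    for sample in samples:
        try:
            rows.append(extract_sample(sample, spec))
        except Exception as exc:  # noqa: BLE001 - re-raised with sample context
            raise ExtractionError(sample.sample_id, str(exc)) from exc
        labels.append(sample.label)
        ids.append(sample.sample_id)
    if not rows:
        raise ValueError("cannot assemble a feature matrix from zero samples")
    values = np.vstack([r.to_numpy() for r in rows])
    fm = FeatureMatrix(values, list(rows[0].index), np.asarray(labels), ids)
    if spec.standardize == "pooled":
        return standardize_matrix(fm)
    if spec.standardize == "train_only" and train_indices is not None:
        return standardize_matrix(fm, train_indices=train_indices)
    return fm


def assemble_matrix(
    manifest: DatasetManifest,
    spec: ExtractorSpec | None = None,
    root: str | Path = ".",
    train_indices: Sequence[int] | None = None,
) -> FeatureMatrix:
    """Load every manifest image and extract its descriptors; rows in manifest order."""
    return extract_features(load_samples(manifest, root), spec, train_indices=train_indices)


def standardize_matrix(fm: FeatureMatrix, train_indices: Sequence[int] | None = None) -> FeatureMatrix:
    """Z-score columns; statistics from ``train_indices`` rows if given, else all rows.

    Columns with zero variance in the reference rows are set to 0.
    """
    ref = fm.values if train_indices is None else fm.values[np.asarray(train_indices, dtype=int)]
    mean = ref.mean(axis=0)
    sd = ref.std(axis=0)
    values = fm.values - mean
    nonzero = sd > 1e-12
    values[:, nonzero] /= sd[nonzero]
    values[:, ~nonzero] = 0.0
    return FeatureMatrix(values, list(fm.feature_names), fm.labels, list(fm.sample_ids))


class DescriptorExtractor(TransformerMixin, BaseEstimator):
    """sklearn-style transformer over lists of :class:`ImageSample`.

    ``fit`` is stateless (the descriptor bank has no learned parameters);
    ``transform`` returns the raw descriptor array. Use
    :func:`extract_features` for the named :class:`FeatureMatrix` container.
    """

    def __init__(
        self,
        families: tuple[str, ...] = FAMILY_ORDER,
        glcm_levels: int = 8,
        glcm_offsets: tuple[tuple[int, int], ...] = ((0, 1), (1, 0)),
    ):
        self.families = families
        self.glcm_levels = glcm_levels
        self.glcm_offsets = glcm_offsets

    def _spec(self) -> ExtractorSpec:
        return ExtractorSpec(
            families=self.families,
            glcm_levels=self.glcm_levels,
            glcm_offsets=self.glcm_offsets,
            standardize="none",
        )

    def fit(self, X, y=None):  # noqa: D102 - sklearn contract
        spec = self._spec()
        self.feature_names_out_ = list(extract_sample(X[0], spec).index) if len(X) else []
        self.n_features_out_ = len(self.feature_names_out_)
        return self

    def transform(self, X) -> np.ndarray:  # noqa: D102 - sklearn contract
        spec = self._spec()
        return np.vstack([extract_sample(s, spec).to_numpy() for s in X])

    def get_feature_names_out(self, input_features=None):  # noqa: D102
        return np.asarray(self.feature_names_out_, dtype=object)
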