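"""Gray-level co-occurrence texture features (Haralick style).

A single-band image is quantized to Ng gray levels by linear min-max
binning, the normalized co-occurrence matrix p(i, j) is tallied for a
fixed pixel offset (default 0 degrees, distance 1, i.e. (dr, dc) = (0, 1)),
and four scalars summarize it:

* contrast     = sum (i - j)^2 p(i, j)
* homogeneity  = sum p(i, j) / (1 + |i - j|)   (inverse-difference form)
* energy       = sum p(i, j)^2
* correlation  = sum (i - mu_i)(j - mu_j) p(i, j) / (sigma_i sigma_j),
  defined as 0 when either marginal is degenerate.

The GLCM is symmetric by default (pair counts plus their transpose),
following the classical definition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .band_selection import BandSet
from .errors import DataError, DimensionError, ParameterError
from .hypercube_io import ROI

__all__ = [
    "LevelImage",
    "GLCM",
    "TextureFeatures",
    "quantize",
    "compute_glcm",
    "glcm_features",
    "texture_vector",
]

FEATURE_NAMES = ("contrast", "homogeneity", "energy", "correlation")


@dataclass
class LevelImage:
    levels: np.ndarray  # 2-D int array in [0, Ng-1]
    Ng: int

    def __post_init__(self):
        self.levels = np.asarray(self.levels)
        if self.levels.ndim != 2:
            raise DimensionError("level image must be 2-D")
        if self.Ng < 2:
            raise ParameterError(f"Ng must be >= 2, got {self.Ng}")
        if self.levels.size and (self.levels.min() < 0 or self.levels.max() >= self.Ng):
            raise ParameterError("levels outside [0, Ng-1]")


@dataclass
class GLCM:
    P: np.ndarray  # Ng x Ng, sums to 1
    offset: tuple[int, int]
    symmetric: bool


@dataclass
class TextureFeatures:
    contrast: float
    homogeneity: float
    energy: float
    correlation: float

    def as_vector(self) -> np.ndarray:
        return np.array([self.contrast, self.homogeneity, self.energy, self.correlation])


def quantize(image: np.ndarray, Ng: int) -> LevelImage:
    """Linear min-max binning to Ng levels; a constant image maps to level 0."""
    image = np.asarray(image, dtype=float)
    if Ng < 2:
        raise ParameterError(f"Ng must be >= 2, got {Ng}")
    if not np.all(np.isfinite(image)):
        raise DataError("image contains non-finite values")
    vmin, vmax = image.min(), image.max()
    if vmax == vmin:
        levels = np.zeros(image.shape, dtype=np.int64)
    else:
        levels = np.floor(Ng * (image - vmin) / (vmax - vmin)).astype(np.int64)
        levels[levels == Ng] = Ng - 1  # the maximum value maps to the top level
    return LevelImage(levels, Ng)


def compute_glcm(
    img: LevelImage, offset: tuple[int, int] = (0, 1), symmetric: bool = True
) -> GLCM:
    """Normalized co-occurrence matrix of gray-level pairs at a fixed offset."""
    dr, dc = offset
    rows, cols = img.levels.shape
    if abs(dr) >= rows or abs(dc) >= cols:
        raise DimensionError(
            f"offset {offset} exceeds image extent {img.levels.shape}"
        )
    a = img.levels[max(0, -dr) : rows - max(0, dr), max(0, -dc) : cols - max(0, dc)]
    b = img.levels[max(0, dr) : rows + min(0, dr), max(0, dc) : cols + min(0, dc)]
    counts = np.bincount(
        (a.ravel() * img.Ng + b.ravel()), minlength=img.Ng * img.Ng
    ).reshape(img.Ng, img.Ng).astype(float)
    if symmetric:
        counts = counts + counts.T
    total = counts.sum()
    if total == 0:
        raise DimensionError("no valid pixel pairs for this offset")
    return GLCM(counts / total, (dr, dc), symmetric)


def glcm_features(g: GLCM) -> TextureFeatures:
    """Contrast, homogeneity, energy and correlation of a normalized GLCM."""
    P = g.P
    Ng = P.shape[0]
    i = np.arange(Ng)[:, None]
    j = np.arange(Ng)[None, :]
    contrast = float(np.sum((i - j) ** 2 * P))
    homogeneity = float(np.sum(P / (1.0 + np.abs(i - j))))
    energy = float(np.sum(P**2))
    px = P.sum(axis=1)
    py = P.sum(axis=0)
    mu_i = float(np.sum(np.arange(Ng) * px))
    mu_j = float(np.sum(np.arange(Ng) * py))
    var_i = float(np.sum((np.arange(Ng) - mu_i) ** 2 * px))
    var_j = float(np.sum((np.arange(Ng) - mu_j) ** 2 * py))
    denom = np.sqrt(var_i * var_j)
    if denom <= 0:
        correlation = 0.0
    else:
        correlation = float(np.sum((i - mu_i) * (j - mu_j) * P) / denom)
    return TextureFeatures(contrast, homogeneity, energy, correlation)


def texture_vector(
    roi: ROI,
    bands: BandSet,
    Ng: int = 8,
    offset: tuple[int, int] = (0, 1),
    symmetric: bool = True,
) -> np.ndarray:
    """Concatenated GLCM features of the ROI at each selected band.

    Band-major order, features ordered (contrast, homogeneity, energy,
    correlation), giving a vector of length 4 * |bands|.
    """
    if len(bands) == 0:
        raise ParameterError("band set is empty")
    if np.any(bands.band_indices < 0) or np.any(bands.band_indices >= roi.cube.n_bands):
        raise DimensionError("band indices outside the ROI's spectral axis")
    parts = []
    for bi in bands.band_indices:
        img = quantize(roi.cube.data[:, :, bi], Ng)
        feats = glcm_features(compute_glcm(img, offset, symmetric))
        parts.append(feats.as_vector())
    return np.concatenate(parts)
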