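"""Optimal-wavelength selection from the loadings of a pixel-spectra PCA.

Here PCA is run on image pixels (each pixel's spectrum is one observation,
bands are the variables). The loading vector of each leading component
weights the original band images; wavelengths sitting at peaks (local
maxima) and valleys (local minima) of those loadings carry the most
variance and are kept as the effective wavelengths, so a handful of
monochromatic images can stand in for the full hypercube.

Selection rule: interior extrema pooled from the first (up to three)
loading columns are ranked by absolute loading value and kept greedily
subject to a minimum pairwise wavelength separation. Extrema at the ends
of the spectral axis are recorded but excluded by default, since the edges
of the usable spectral range are noise-prone.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import DimensionError, ParameterError
from .hypercube_io import ROI
from .spectral_features import PCAModel, fit_pca

__all__ = [
    "LoadingProfile",
    "BandSet",
    "ExtremumRecord",
    "fit_image_pca",
    "fit_montage_pca",
    "find_loading_extrema",
    "find_loading_extrema_records",
    "select_bands",
]


@dataclass(frozen=True)
class ExtremumRecord:
    index: int
    kind: str  # "max" | "min"
    pc: int  # 0-based loading column
    value: float  # loading value at the extremum
    interior: bool


@dataclass
class LoadingProfile:
    """Loading matrix (p bands x k PCs) of a pixel-spectra PCA, with wavelengths."""

    loadings: np.ndarray
    wavelengths: np.ndarray
    model: PCAModel | None = None

    def __post_init__(self):
        self.loadings = np.asarray(self.loadings, dtype=float)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        if self.loadings.ndim != 2 or self.loadings.shape[0] != len(self.wavelengths):
            raise DimensionError(
                f"loadings shape {self.loadings.shape} incompatible with "
                f"{len(self.wavelengths)} wavelengths"
            )


@dataclass
class BandSet:
    """Selected effective wavelengths, sorted ascending, with provenance."""

    wavelengths: np.ndarray
    band_indices: np.ndarray
    provenance: list[ExtremumRecord] = field(default_factory=list)
    shortfall: bool = False

    def __len__(self) -> int:
        return len(self.band_indices)

    def to_json(self, path=None) -> str:
        payload = [
            {
                "wavelength_nm": float(w),
                "band_index": int(i),
                "pc": int(rec.pc),
                "kind": rec.kind,
            }
            for w, i, rec in zip(self.wavelengths, self.band_indices, self.provenance)
        ]
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def fit_image_pca(roi: ROI, k: int) -> LoadingProfile:
    """PCA with the ROI's pixels as observations and bands as variables."""
    if roi.cube.kind != "reflectance":
        raise ParameterError("fit_image_pca expects a reflectance ROI")
    p = roi.cube.n_bands
    pixels = roi.cube.data.reshape(-1, p)
    model = fit_pca(pixels, k)
    return LoadingProfile(model.loadings, roi.cube.wavelengths, model)


def fit_montage_pca(
    rois: list[ROI], k: int, pixels_per_roi: int | None = None, seed: int = 0
) -> LoadingProfile:
    """Dataset-level pixel PCA: stack (optionally subsampled) pixels of many ROIs.

    Fitting one PCA on a montage of all calibration ROIs yields a single
    global band set rather than one per image.
    """
    if not rois:
        raise ParameterError("need at least one ROI")
    wl = rois[0].cube.wavelengths
    rng = np.random.default_rng(seed)
    blocks = []
    for roi in rois:
        if roi.cube.kind != "reflectance":
            raise ParameterError("fit_montage_pca expects reflectance ROIs")
        px = roi.cube.data.reshape(-1, roi.cube.n_bands)
        if pixels_per_roi is not None and pixels_per_roi < px.shape[0]:
            idx = rng.choice(px.shape[0], size=pixels_per_roi, replace=False)
            px = px[np.sort(idx)]
        blocks.append(px)
    model = fit_pca(np.vstack(blocks), k)
    return LoadingProfile(model.loadings, wl, model)


def find_loading_extrema_records(loading: np.ndarray, window: int = 11, pc: int = 0):
    """All local maxima/minima of a loading vector within a centered window.

    A point is an extremum when it attains the window max (or min) and no
    earlier point in its window ties it — plateaus resolve to the lowest
    index. Endpoints are eligible through the truncated window and are
    flagged non-interior.
    """
    loading = np.asarray(loading, dtype=float)
    p = loading.shape[0]
    if window < 3 or window % 2 == 0:
        raise ParameterError(f"window must be odd and >= 3, got {window}")
    if p < window:
        raise ParameterError(f"loading length {p} shorter than window {window}")
    half = window // 2
    records = []
    for i in range(p):
        lo, hi = max(0, i - half), min(p, i + half + 1)
        seg = loading[lo:hi]
        before = loading[lo:i]
        if loading[i] == seg.max() and not np.any(before == loading[i]):
            records.append(
                ExtremumRecord(i, "max", pc, float(loading[i]), 0 < i < p - 1)
            )
        if loading[i] == seg.min() and not np.any(before == loading[i]):
            records.append(
                ExtremumRecord(i, "min", pc, float(loading[i]), 0 < i < p - 1)
            )
    return records


def find_loading_extrema(loading: np.ndarray, window: int = 11) -> list[int]:
    """Indices of the local extrema of a loading vector (see records variant)."""
    return sorted({rec.index for rec in find_loading_extrema_records(loading, window)})


def select_bands(
    profile: LoadingProfile,
    k_bands: int = 3,
    merge_window_nm: float = 10.0,
    window: int = 11,
    include_endpoints: bool = False,
) -> BandSet:
    """Pick ``k_bands`` effective wavelengths from the leading loading extrema.

    Candidates are the extrema of the first min(3, k) loading columns,
    ranked by |loading| (ties broken by band index), kept greedily while
    enforcing a pairwise wavelength separation of ``merge_window_nm``.
    Fewer candidates than requested returns them all with a shortfall flag.
    """
    if k_bands < 1:
        raise ParameterError(f"k_bands must be >= 1, got {k_bands}")
    n_pcs = min(3, profile.loadings.shape[1])
    candidates: dict[int, ExtremumRecord] = {}
    for pc in range(n_pcs):
        for rec in find_loading_extrema_records(profile.loadings[:, pc], window, pc):
            if not rec.interior and not include_endpoints:
                continue
            prev = candidates.get(rec.index)
            if prev is None or abs(rec.value) > abs(prev.value):
                candidates[rec.index] = rec

    ranked = sorted(candidates.values(), key=lambda r: (-abs(r.value), r.index))
    kept: list[ExtremumRecord] = []
    for rec in ranked:
        wl = profile.wavelengths[rec.index]
        if all(
            abs(wl - profile.wavelengths[k.index]) >= merge_window_nm for k in kept
        ):
            kept.append(rec)
        if len(kept) == k_bands:
            break

    shortfall = len(kept) < k_bands
    if shortfall:
        warnings.warn(
            f"only {len(kept)} candidate bands available, {k_bands} requested",
            RuntimeWarning,
            stacklevel=2,
        )
    kept.sort(key=lambda r: profile.wavelengths[r.index])
    idx = np.array([r.index for r in kept], dtype=int)
    return BandSet(profile.wavelengths[idx], idx, kept, shortfall)
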