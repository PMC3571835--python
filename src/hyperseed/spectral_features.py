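"""Mean-spectrum extraction and spectral feature compression by PCA and RBF-KPCA.

Each square ROI contributes one sample: its per-band arithmetic mean over
all pixels is the sample's average reflectance spectrum. PCA compresses the
resulting samples x bands matrix by a mean-centered singular-value
decomposition; kernel PCA does the same implicitly in the feature space of
a Gaussian RBF kernel, via the double-centered kernel matrix.

Conventions
-----------
* PCA loadings carry a deterministic sign: each column is flipped so its
  largest-magnitude element is positive. KPCA eigenvectors follow the same
  rule. This removes the sign ambiguity of eigen-decompositions.
* The KPCA kernel is k(u, v) = exp(-||u - v||^2 / (2 * sigma2)), i.e.
  sigma2 is a variance scale. (The LS-SVM classifier module uses the
  divisor sigma2 without the factor 2 — see that module's docstring.)
* sigma2="auto" applies the median heuristic: the median of all pairwise
  squared distances between training rows.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist, pdist

from .errors import DimensionError, ParameterError
from .hypercube_io import ROI

__all__ = [
    "SpectrumTable",
    "PCAModel",
    "KPCAModel",
    "mean_spectrum",
    "fit_pca",
    "project_pca",
    "fit_kpca",
    "project_kpca",
]


@dataclass
class SpectrumTable:
    """ROI mean spectra: n samples x p bands, with wavelengths and optional labels."""

    X: np.ndarray
    wavelengths: np.ndarray
    labels: np.ndarray | None = None

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        if self.X.ndim != 2 or self.X.shape[1] != len(self.wavelengths):
            raise DimensionError(
                f"X shape {self.X.shape} incompatible with {len(self.wavelengths)} wavelengths"
            )
        if not np.all(np.isfinite(self.X)):
            raise DimensionError("spectrum table contains non-finite values")
        if self.labels is not None:
            self.labels = np.asarray(self.labels)
            if len(self.labels) != self.X.shape[0]:
                raise DimensionError("label count does not match sample count")

    def to_csv(self, path) -> None:
        cols = {"sample_id": np.arange(self.X.shape[0])}
        cols["label"] = self.labels if self.labels is not None else [""] * self.X.shape[0]
        frame = pd.DataFrame(cols)
        wl_cols = pd.DataFrame(self.X, columns=[f"{w:.6g}" for w in self.wavelengths])
        pd.concat([frame, wl_cols], axis=1).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "SpectrumTable":
        frame = pd.read_csv(path)
        wl = np.array([float(c) for c in frame.columns[2:]])
        labels = frame["label"].to_numpy()
        if pd.isna(labels).all() or (labels == "").all():
            labels = None
        return cls(frame.iloc[:, 2:].to_numpy(float), wl, labels)


def mean_spectrum(roi: ROI) -> np.ndarray:
    """Average reflectance spectrum of an ROI: per-band mean over all pixels."""
    if roi.cube.kind != "reflectance":
        raise ParameterError("mean_spectrum expects a reflectance ROI")
    if roi.cube.data.size == 0:
        raise DimensionError("empty ROI")
    return roi.cube.data.mean(axis=(0, 1))


# ---------------------------------------------------------------------------
# PCA


@dataclass
class PCAModel:
    mean: np.ndarray
    loadings: np.ndarray  # p x k, columns orthonormal
    explained_variance_ratio: np.ndarray
    training_scores: np.ndarray = field(repr=False, default=None)


def _fix_signs(vectors: np.ndarray) -> np.ndarray:
    """Flip each column so its largest-magnitude element is positive."""
    idx = np.argmax(np.abs(vectors), axis=0)
    signs = np.sign(vectors[idx, np.arange(vectors.shape[1])])
    signs[signs == 0] = 1.0
    return signs


def fit_pca(X: np.ndarray, k: int) -> PCAModel:
    """PCA by SVD of the mean-centered data matrix.

    Requires n >= 2 samples and k <= min(n - 1, p).
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if n < 2:
        raise ParameterError(f"PCA needs at least 2 samples, got {n}")
    if not 1 <= k <= min(n - 1, p):
        raise ParameterError(f"k={k} must be in [1, min(n-1, p)] = [1, {min(n - 1, p)}]")
    mean = X.mean(axis=0)
    u, s, vt = np.linalg.svd(X - mean, full_matrices=False)
    total = np.sum(s**2)
    evr = s**2 / total if total > 0 else np.zeros_like(s)
    loadings = vt[:k].T
    signs = _fix_signs(loadings)
    loadings = loadings * signs
    scores = (u[:, :k] * s[:k]) * signs
    return PCAModel(mean, loadings, evr[:k], scores)


def project_pca(model: PCAModel, X: np.ndarray) -> np.ndarray:
    """Project rows of X onto the fitted loadings: (X - mean) @ loadings."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != model.mean.shape[0]:
        raise DimensionError(
            f"X has {X.shape[-1] if X.ndim == 2 else '?'} bands, model expects "
            f"{model.mean.shape[0]}"
        )
    return (X - model.mean) @ model.loadings


# ---------------------------------------------------------------------------
# Kernel PCA


@dataclass
class KPCAModel:
    training_X: np.ndarray
    sigma2: float  # RBF variance scale; ignored for the linear test kernel
    alphas: np.ndarray  # n x k, eigenvectors scaled by 1/sqrt(eigenvalue)
    eigenvalues: np.ndarray
    kernel_col_means: np.ndarray  # per-column means of the uncentered training kernel
    kernel_grand_mean: float
    kernel: str = "rbf"
    training_scores: np.ndarray = field(repr=False, default=None)
    warnings: list = field(default_factory=list)


def _kernel_matrix(A: np.ndarray, B: np.ndarray, kernel: str, sigma2: float) -> np.ndarray:
    if kernel == "linear":
        return A @ B.T
    d2 = cdist(A, B, metric="sqeuclidean")
    return np.exp(-d2 / (2.0 * sigma2))


def fit_kpca(
    X: np.ndarray,
    sigma2: float | str = "auto",
    k: int = 3,
    kernel: str = "rbf",
) -> KPCAModel:
    """Kernel PCA on the double-centered kernel matrix.

    Eigenvectors are scaled by 1/sqrt(eigenvalue) so feature-space
    components have unit norm; the training scores are then the rows of
    (centered K) @ alphas. ``kernel="linear"`` is a test hook that makes
    the procedure coincide with ordinary PCA up to column signs.
    """
    X = np.asarray(X, dtype=float)
    n, _ = X.shape
    if n < 3:
        raise ParameterError(f"KPCA needs at least 3 samples, got {n}")
    if not 1 <= k <= n - 1:
        raise ParameterError(f"k={k} must be in [1, n-1] = [1, {n - 1}]")
    if kernel not in ("rbf", "linear"):
        raise ParameterError(f"kernel must be 'rbf' or 'linear', got {kernel!r}")
    if kernel == "rbf":
        if sigma2 == "auto":
            d2 = pdist(X, metric="sqeuclidean")
            med = float(np.median(d2)) if d2.size else 0.0
            sigma2 = med if med > 0 else 1.0
        sigma2 = float(sigma2)
        if sigma2 <= 0:
            raise ParameterError(f"sigma2 must be positive, got {sigma2}")
    else:
        sigma2 = float("nan")

    K = _kernel_matrix(X, X, kernel, sigma2)
    col_means = K.mean(axis=0)
    grand = float(K.mean())
    Kc = K - col_means[None, :] - col_means[:, None] + grand

    eigvals, eigvecs = np.linalg.eigh(Kc)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]

    tol = max(1e-12, 1e-10 * max(eigvals[0], 0.0))
    n_pos = int(np.count_nonzero(eigvals > tol))
    warn_records = []
    if n_pos < k:
        warn_records.append(
            f"requested {k} components but only {n_pos} positive eigenvalues; reduced"
        )
        warnings.warn(warn_records[-1], RuntimeWarning, stacklevel=2)
        k = max(n_pos, 1)
    eigvals, eigvecs = eigvals[:k], eigvecs[:, :k]
    eigvecs = eigvecs * _fix_signs(eigvecs)
    alphas = eigvecs / np.sqrt(np.maximum(eigvals, tol))

    model = KPCAModel(
        training_X=X,
        sigma2=sigma2,
        alphas=alphas,
        eigenvalues=eigvals,
        kernel_col_means=col_means,
        kernel_grand_mean=grand,
        kernel=kernel,
        warnings=warn_records,
    )
    model.training_scores = Kc @ alphas
    return model


def project_kpca(model: KPCAModel, X: np.ndarray) -> np.ndarray:
    """Out-of-sample KPCA scores using the stored training centering statistics."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != model.training_X.shape[1]:
        raise DimensionError(
            f"X has {X.shape[-1] if X.ndim == 2 else '?'} bands, model expects "
            f"{model.training_X.shape[1]}"
        )
    if X.shape[0] == 0:
        return np.zeros((0, model.alphas.shape[1]))
    K = _kernel_matrix(X, model.training_X, model.kernel, model.sigma2)
    Kc = (
        K
        - model.kernel_col_means[None, :]
        - K.mean(axis=1, keepdims=True)
        + model.kernel_grand_mean
    )
    return Kc @ model.alphas
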