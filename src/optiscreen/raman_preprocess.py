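"""Spectral pre-treatment for hyperspectral Raman maps.

Every pixel of a Raman map is a spectrum over a common wavenumber axis.
The standard pre-treatment before classification is: crop to the
fingerprint region, subtract the slowly varying fluorescence background
with the SNIP algorithm (statistics-sensitive non-linear iterative
peak-clipping), scale each spectrum to unit Euclidean norm, and compress
the result with a principal component analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from sklearn.decomposition import PCA as _SkPCA

logger = logging.getLogger(__name__)


@dataclass
class RamanMap:
    """Spatial grid of Raman spectra from one scan of one individual.

    ``spectra`` has one row per pixel in row-major grid order; the row
    count equals ``rows * cols`` of ``grid_shape``.
    """

    spectra: np.ndarray  # (n_pixels, n_wavenumbers)
    wavenumbers: np.ndarray  # cm^-1, strictly increasing
    grid_shape: tuple[int, int]
    individual_id: str
    scan_id: str
    pixel_labels: np.ndarray | None = None  # per-pixel class, optional
    valid: np.ndarray | None = None  # per-pixel validity flag

    def __post_init__(self) -> None:
        self.spectra = np.asarray(self.spectra, dtype=float)
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float)
        self.grid_shape = (int(self.grid_shape[0]), int(self.grid_shape[1]))
        rows, cols = self.grid_shape
        if rows <= 0 or cols <= 0:
            raise ValueError("grid_shape must be positive")
        if self.spectra.shape != (rows * cols, self.wavenumbers.size):
            raise ValueError(
                f"spectra shape {self.spectra.shape} inconsistent with grid "
                f"{self.grid_shape} and {self.wavenumbers.size} wavenumbers"
            )
        if np.any(np.diff(self.wavenumbers) <= 0):
            raise ValueError("wavenumber axis must be strictly increasing")
        if not np.all(np.isfinite(self.spectra)):
            raise ValueError("spectra must be finite")
        if self.pixel_labels is not None:
            self.pixel_labels = np.asarray(self.pixel_labels)
            if self.pixel_labels.shape[0] != self.spectra.shape[0]:
                raise ValueError("pixel_labels length mismatch")

    @property
    def n_pixels(self) -> int:
        return self.spectra.shape[0]


def _lls(y: np.ndarray) -> np.ndarray:
    return np.log(np.log(np.sqrt(y + 1.0) + 1.0) + 1.0)


def _lls_inv(v: np.ndarray) -> np.ndarray:
    return np.square(np.exp(np.exp(v) - 1.0) - 1.0) - 1.0


def snip_baseline(
    spectrum: np.ndarray,
    iterations: int = 30,
    lls: bool = True,
    decreasing: bool = True,
) -> np.ndarray:
    """Estimate a smooth baseline by iterative peak clipping (SNIP).

    At clipping window ``p`` every interior point is replaced by the
    minimum of itself and the mean of its neighbours at distance ``p``;
    the window shrinks from ``iterations`` down to 1 (the
    peak-erosion-reducing variant), optionally after the compressing
    log-log-sqrt (LLS) transform.  Peaks narrower than the maximum
    window are clipped out of the estimate, so ``spectrum - baseline``
    retains them.  The maximum window must exceed the half-width of the
    widest peak; overly large values progressively clip genuine baseline
    curvature into the corrected signal, hence the moderate default.

    Accepts a single spectrum or a (n_spectra, n_points) matrix.
    """
    iterations = int(iterations)
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    y = np.asarray(spectrum, dtype=float)
    squeeze = y.ndim == 1
    y2 = np.atleast_2d(y)
    n = y2.shape[1]
    if n <= 2 * iterations:
        raise ValueError(
            f"spectrum length {n} too short for {iterations} iterations"
        )
    v = _lls(np.maximum(y2, -1.0)) if lls else y2.copy()
    v0 = v.copy()
    windows = range(iterations, 0, -1) if decreasing else range(1, iterations + 1)
    for p in windows:
        avg = 0.5 * (v[:, : -2 * p] + v[:, 2 * p :])
        np.minimum(v[:, p:-p], avg, out=v[:, p:-p])
    if lls:
        base = _lls_inv(v)
        # points never clipped are returned bit-exact (avoids transform
        # round-trip error, e.g. on constant spectra)
        base = np.where(v == v0, y2, base)
    else:
        base = v
    return base[0] if squeeze else base


def vector_normalize(spectrum: np.ndarray) -> np.ndarray:
    """Scale spectra to unit Euclidean norm (direction preserved).

    Accepts a single spectrum or a matrix of row spectra; raises on a
    zero-norm spectrum (callers that must tolerate these flag them via
    :func:`preprocess_map`).
    """
    s = np.asarray(spectrum, dtype=float)
    norm = np.linalg.norm(s, axis=-1, keepdims=True)
    if np.any(norm == 0):
        raise ValueError("zero-norm spectrum cannot be normalized")
    return s / norm


def preprocess_map(
    rmap: RamanMap,
    snip_iterations: int = 30,
    crop_range: tuple[float, float] = (600.0, 1800.0),
    lls: bool = True,
) -> RamanMap:
    """Crop, SNIP-subtract and vector-normalize every spectrum of a map.

    Spectra with zero norm after background subtraction are flagged
    invalid (``valid`` mask) and left as zeros; downstream stages drop
    them.  Deterministic.
    """
    lo, hi = crop_range
    sel = (rmap.wavenumbers >= lo) & (rmap.wavenumbers <= hi)
    if not np.any(sel):
        raise ValueError(f"crop range {crop_range} outside wavenumber axis")
    wn = rmap.wavenumbers[sel]
    spectra = rmap.spectra[:, sel]
    baseline = snip_baseline(spectra, iterations=snip_iterations, lls=lls)
    corrected = spectra - baseline
    norms = np.linalg.norm(corrected, axis=1)
    valid = norms > 1e-12
    out = np.zeros_like(corrected)
    out[valid] = corrected[valid] / norms[valid, None]
    n_bad = int((~valid).sum())
    if n_bad:
        logger.info(
            "preprocess_map %s/%s: flagged %d invalid spectra",
            rmap.individual_id,
            rmap.scan_id,
            n_bad,
        )
    return replace(rmap, spectra=out, wavenumbers=wn, valid=valid)


@dataclass
class PCAModel:
    """Mean spectrum plus orthonormal loadings with a fixed sign convention.

    Each loading's largest-magnitude element is positive; explained
    variance fractions are non-increasing.
    """

    mean: np.ndarray
    components: np.ndarray  # (n_components, n_features), orthonormal rows
    explained_variance_ratio: np.ndarray
    n_components: int


def fit_pca(spectra: np.ndarray, n_components: int) -> PCAModel:
    """Mean-centred PCA via SVD."""
    X = np.asarray(spectra, dtype=float)
    if n_components > min(X.shape):
        raise ValueError(
            f"n_components={n_components} exceeds min(n_spectra, n_features)"
            f"={min(X.shape)}"
        )
    solver = "covariance_eigh" if X.shape[1] <= X.shape[0] else "full"
    sk = _SkPCA(n_components=n_components, svd_solver=solver).fit(X)
    comps = sk.components_.copy()
    for i in range(comps.shape[0]):
        j = np.argmax(np.abs(comps[i]))
        if comps[i, j] < 0:
            comps[i] = -comps[i]
    return PCAModel(
        mean=sk.mean_,
        components=comps,
        explained_variance_ratio=sk.explained_variance_ratio_,
        n_components=n_components,
    )


def project_pca(model: PCAModel, spectra: np.ndarray) -> np.ndarray:
    """Scores of spectra in the PCA basis: (X - mean) @ loadings^T."""
    X = np.asarray(spectra, dtype=float)
    return (X - model.mean) @ model.components.T


def reconstruct_pca(model: PCAModel, scores: np.ndarray) -> np.ndarray:
    """Inverse of :func:`project_pca` within the retained subspace."""
    return np.asarray(scores, dtype=float) @ model.components + model.mean


def choose_n_components(
    spectra: np.ndarray, variance_threshold: float = 0.99, cap: int = 20
) -> int:
    """Smallest component count reaching the variance threshold, capped."""
    X = np.asarray(spectra, dtype=float)
    solver = "covariance_eigh" if X.shape[1] <= X.shape[0] else "full"
    full = _SkPCA(n_components=min(cap, *X.shape), svd_solver=solver).fit(X)
    cum = np.cumsum(full.explained_variance_ratio_)
    idx = int(np.searchsorted(cum, variance_threshold)) + 1
    return min(idx, cap, *X.shape)
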