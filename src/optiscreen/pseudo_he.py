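"""Virtual H&E staining of preprocessed multimodal images.

Three models cooperate (all trained on a single annotated image in the
intended workflow):

* a partial-least-squares (PLS) regression with 3 components maps the
  three multimodal channels to H&E RGB values;
* a two-class linear discriminant analysis (LDA) on the raw channel
  intensities detects cell nuclei, which carry negative contrast in all
  three channels and are painted dark violet;
* a k-means segmentation (k=6, darkest cluster = background) followed by
  median filtering, morphological closing/opening and a mean filter
  yields a smooth background weighting mask used to fade large empty
  areas to white.

The composite is ``bg*white + (1-bg)*(nucleus ? violet : color)`` per
pixel, a convex combination, so the output always stays in [0, 1].
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.morphology import disk
from sklearn.cluster import KMeans
from sklearn.cross_decomposition import PLSRegression

from .mm_preprocess import MultimodalImage

#: default dark-violet for nuclei (the stain names the hue, not the RGB)
DEFAULT_NUCLEI_COLOR = (0.29, 0.13, 0.37)


# --------------------------------------------------------------------------
# PLS color model
# --------------------------------------------------------------------------


@dataclass
class ColorModel:
    """Affine RGB predictor distilled from a PLS2 regression.

    ``predict = clip(X @ coef.T + intercept)`` with ``coef`` of shape
    (3 outputs, 3 inputs).
    """

    coef: np.ndarray
    intercept: np.ndarray
    n_components: int
    training_rmse: float
    trained: bool = True


def fit_color_model(
    mm: MultimodalImage,
    he: np.ndarray,
    n_components: int = 3,
    mask: np.ndarray | None = None,
) -> ColorModel:
    """Fit a PLS2 regression of H&E RGB on the three multimodal channels.

    ``mm`` and ``he`` must be pixel-registered and share spatial shape;
    ``mask`` (optional) restricts training to foreground pixels.  With
    full-rank inputs and 3 components the fit coincides with ordinary
    least squares; rank-deficient inputs reduce the component count with
    a warning.
    """
    he = np.asarray(he, dtype=float)
    if he.shape[:2] != mm.shape or he.shape[-1] != 3:
        raise ValueError(f"he shape {he.shape} does not match image {mm.shape}")
    if not 1 <= n_components <= 3:
        raise ValueError("n_components must be in {1, 2, 3}")
    X = mm.data.reshape(-1, 3)
    Y = he.reshape(-1, 3)
    if mask is not None:
        flat = np.asarray(mask, dtype=bool).ravel()
        X, Y = X[flat], Y[flat]
    if X.shape[0] < 4:
        raise ValueError("need at least 4 training pixels")
    rank = np.linalg.matrix_rank(X - X.mean(axis=0))
    if rank < n_components:
        warnings.warn(
            f"input rank {rank} < n_components {n_components}; reducing",
            stacklevel=2,
        )
        n_components = max(1, rank)
    pls = PLSRegression(n_components=n_components).fit(X, Y)
    pred = pls.predict(X)
    rmse = float(np.sqrt(np.mean((pred - Y) ** 2)))
    # distil the fitted model (which operates on centred inputs) into a
    # plain affine map: y = x @ coef.T + intercept
    coef = np.asarray(pls.coef_, dtype=float)
    intercept = np.asarray(pls.intercept_, dtype=float) - np.asarray(
        pls._x_mean, dtype=float
    ) @ coef.T
    return ColorModel(
        coef=coef,
        intercept=intercept,
        n_components=n_components,
        training_rmse=rmse,
    )


def predict_color(model: ColorModel, mm: MultimodalImage) -> np.ndarray:
    """Per-pixel affine RGB prediction, clipped to [0, 1]."""
    if not model.trained:
        raise ValueError("color model is not trained")
    X = mm.data.reshape(-1, 3)
    rgb = X @ model.coef.T + model.intercept
    return np.clip(rgb, 0.0, 1.0).reshape(mm.shape + (3,))


# --------------------------------------------------------------------------
# LDA nuclei model
# --------------------------------------------------------------------------


@dataclass
class NucleiModel:
    """Two-class Gaussian LDA (pooled covariance) over channel intensities.

    Class 1 is "nucleus"; the decision applies a threshold on the
    posterior probability and a minimum-object-area filter.
    """

    means: np.ndarray  # (2, 3): rows (not-nucleus, nucleus)
    pooled_cov: np.ndarray  # (3, 3)
    log_priors: np.ndarray  # (2,)
    threshold: float = 0.5
    min_area: int = 4
    trained: bool = True

    def discriminant(self) -> tuple[np.ndarray, float]:
        """Weights/bias of the affine decision functional w.x + b
        (positive means nucleus at threshold 0.5)."""
        inv = np.linalg.inv(self.pooled_cov)
        w = inv @ (self.means[1] - self.means[0])
        b = (
            -0.5 * (self.means[1] @ inv @ self.means[1])
            + 0.5 * (self.means[0] @ inv @ self.means[0])
            + self.log_priors[1]
            - self.log_priors[0]
        )
        return w, float(b)

    def posterior(self, pixels: np.ndarray) -> np.ndarray:
        """P(nucleus | intensity) per row of ``pixels``."""
        w, b = self.discriminant()
        z = np.asarray(pixels, dtype=float) @ w + b
        out = np.empty_like(z)
        pos = z >= 0
        out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
        ez = np.exp(z[~pos])
        out[~pos] = ez / (1.0 + ez)
        return out


def fit_nuclei_model(
    pixels: np.ndarray,
    labels: np.ndarray,
    threshold: float = 0.5,
    min_area: int = 4,
    ridge: float = 1e-6,
) -> NucleiModel:
    """Fit the two-class LDA from labelled 3-channel samples.

    ``labels`` is boolean (True = nucleus); both classes need >= 10
    samples.  A singular pooled covariance is ridge-regularized on the
    diagonal with ``ridge * trace/3`` and a warning.
    """
    X = np.asarray(pixels, dtype=float).reshape(-1, 3)
    y = np.asarray(labels, dtype=bool).ravel()
    if X.shape[0] != y.shape[0]:
        raise ValueError("pixels/labels length mismatch")
    n1, n0 = int(y.sum()), int((~y).sum())
    if min(n0, n1) < 10:
        raise ValueError("need >= 10 samples per class")
    m0, m1 = X[~y].mean(axis=0), X[y].mean(axis=0)
    d0, d1 = X[~y] - m0, X[y] - m1
    cov = (d0.T @ d0 + d1.T @ d1) / (n0 + n1 - 2)
    if np.linalg.cond(cov) > 1e10:
        warnings.warn("singular pooled covariance; ridge-regularizing", stacklevel=2)
        cov = cov + ridge * (np.trace(cov) / 3.0) * np.eye(3)
    priors = np.log([n0 / (n0 + n1), n1 / (n0 + n1)])
    return NucleiModel(
        means=np.stack([m0, m1]),
        pooled_cov=cov,
        log_priors=priors,
        threshold=threshold,
        min_area=min_area,
    )


def predict_nuclei_mask(
    model: NucleiModel,
    mm: MultimodalImage,
    exclude: np.ndarray | None = None,
) -> np.ndarray:
    """Per-pixel posterior thresholding plus minimum-area filtering.

    ``exclude`` (optional boolean mask) suppresses detections, e.g. in
    background regions whose intensities overlap the dark-nucleus
    fingerprint.  A threshold >= 1 yields an empty mask.
    """
    if not model.trained:
        raise ValueError("nuclei model is not trained")
    if model.threshold >= 1.0:
        return np.zeros(mm.shape, dtype=bool)
    post = model.posterior(mm.data.reshape(-1, 3)).reshape(mm.shape)
    mask = post >= model.threshold
    if exclude is not None:
        mask &= ~np.asarray(exclude, dtype=bool)
    if model.min_area > 1:
        lab, n = ndimage.label(mask)
        if n:
            sizes = ndimage.sum_labels(mask, lab, index=np.arange(1, n + 1))
            small = np.flatnonzero(sizes < model.min_area) + 1
            mask &= ~np.isin(lab, small)
    return mask


# --------------------------------------------------------------------------
# background weighting mask
# --------------------------------------------------------------------------


def estimate_background_weight(
    mm: MultimodalImage,
    k: int = 6,
    median_radius: int = 2,
    close_radius: int = 5,
    open_radius: int = 5,
    mean_radius: int = 7,
    seed: int = 0,
) -> np.ndarray:
    """Smooth background weight in [0, 1] (1 = background).

    The image is segmented by k-means (k=6 default, k-means++ with 10
    restarts); the darkest cluster — minimal sum of squared center — is
    background.  The binary mask is median filtered, the foreground is
    morphologically closed (filling gaps and extending it), the
    background mask is opened, and a disk mean filter converts the mask
    into smooth weights.  ``mean_radius=0`` leaves the mask binary.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    X = mm.data.reshape(-1, 3)
    n_distinct = np.unique(X, axis=0).shape[0]
    if n_distinct < k:
        warnings.warn(
            f"only {n_distinct} distinct pixel values; reducing k from {k}",
            stacklevel=2,
        )
        k = max(2, n_distinct)
    km = KMeans(n_clusters=k, init="k-means++", n_init=10, random_state=seed).fit(X)
    bg_cluster = int(np.argmin((km.cluster_centers_**2).sum(axis=1)))
    mask = (km.labels_ == bg_cluster).reshape(mm.shape)
    if median_radius > 0:
        mask = ndimage.median_filter(mask, footprint=disk(median_radius))
    if close_radius > 0:
        fg = ndimage.binary_closing(~mask, structure=disk(close_radius))
        mask = ~fg
    if open_radius > 0:
        mask = ndimage.binary_opening(mask, structure=disk(open_radius))
    weight = mask.astype(float)
    if mean_radius > 0:
        kern = disk(mean_radius).astype(float)
        weight = ndimage.convolve(weight, kern / kern.sum(), mode="nearest")
    return np.clip(weight, 0.0, 1.0)


# --------------------------------------------------------------------------
# compositing
# --------------------------------------------------------------------------


def compose_pseudo_he(
    color: np.ndarray,
    nuclei_mask: np.ndarray,
    background_weight: np.ndarray,
    nuclei_color=DEFAULT_NUCLEI_COLOR,
) -> np.ndarray:
    """Blend color layer, nuclei overlay and white background.

    ``out = bg*white + (1-bg)*(nucleus ? nuclei_color : color)`` per
    pixel and channel.
    """
    color = np.asarray(color, dtype=float)
    nuclei_mask = np.asarray(nuclei_mask, dtype=bool)
    w = np.asarray(background_weight, dtype=float)
    if color.shape[:2] != nuclei_mask.shape or color.shape[:2] != w.shape:
        raise ValueError("layer shapes do not match")
    base = np.where(nuclei_mask[..., None], np.asarray(nuclei_color, dtype=float), color)
    return w[..., None] * 1.0 + (1.0 - w[..., None]) * base


# --------------------------------------------------------------------------
# persistence
# --------------------------------------------------------------------------


def save_models(path, color: ColorModel | None, nuclei: NucleiModel | None) -> None:
    """Serialize the trained staining models to JSON."""
    payload = {}
    if color is not None:
        payload["color"] = {
            "coef": color.coef.tolist(),
            "intercept": color.intercept.tolist(),
            "n_components": color.n_components,
            "training_rmse": color.training_rmse,
        }
    if nuclei is not None:
        payload["nuclei"] = {
            "means": nuclei.means.tolist(),
            "pooled_cov": nuclei.pooled_cov.tolist(),
            "log_priors": nuclei.log_priors.tolist(),
            "threshold": nuclei.threshold,
            "min_area": nuclei.min_area,
        }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)


def load_models(path) -> tuple[ColorModel | None, NucleiModel | None]:
    with open(path) as fh:
        payload = json.load(fh)
    color = nuclei = None
    if "color" in payload:
        c = payload["color"]
        color = ColorModel(
            coef=np.asarray(c["coef"]),
            intercept=np.asarray(c["intercept"]),
            n_components=int(c["n_components"]),
            training_rmse=float(c["training_rmse"]),
        )
    if "nuclei" in payload:
        n = payload["nuclei"]
        nuclei = NucleiModel(
            means=np.asarray(n["means"]),
            pooled_cov=np.asarray(n["pooled_cov"]),
            log_priors=np.asarray(n["log_priors"]),
            threshold=float(n["threshold"]),
            min_area=int(n["min_area"]),
        )
    return color, nuclei
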