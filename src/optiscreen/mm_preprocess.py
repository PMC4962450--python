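"""Preprocessing of tiled nonlinear multimodal microscopy images.

A multimodal image carries three co-registered label-free contrasts —
CARS (lipid-sensitive, rendered red), TPEF (autofluorescence, green) and
SHG (fibrillar collagen, blue) — acquired as a mosaic of square tiles.
Before a virtual H&E stain can be computed the raw mosaic is denoised,
downsampled, corrected for the uneven illumination of the individual
tile scans, and contrast-stretched per channel.  The pipeline order is
fixed: median filter -> downsample -> illumination correction ->
contrast adjustment.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

logger = logging.getLogger(__name__)

#: canonical channel order and false-color assignment
CHANNEL_ROLES = ("CARS", "TPEF", "SHG")  # -> red, green, blue

#: default per-channel (low_tail, high_tail) saturation fractions
DEFAULT_CONTRAST = {
    "CARS": (0.05, 0.015),
    "TPEF": (0.05, 0.04),
    "SHG": (0.001, 0.001),
}


@dataclass
class MultimodalImage:
    """Three-channel float image with tile-grid metadata.

    Parameters
    ----------
    data : ndarray, shape (rows, cols, 3)
        Channel order is (CARS, TPEF, SHG); intensities finite, >= 0.
    tile_shape : tuple of int
        Side lengths (rows, cols) of one tile scan in pixels.
    pixel_size : float, optional
        Micrometres per pixel; metadata only.
    provenance : str
        Free-text processing history.
    """

    data: np.ndarray
    tile_shape: tuple[int, int]
    pixel_size: float | None = None
    provenance: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3 or self.data.shape[2] != 3:
            raise ValueError(f"expected (rows, cols, 3) array, got {self.data.shape}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("intensities must be finite")
        if np.any(self.data < 0):
            raise ValueError("intensities must be non-negative")
        self.tile_shape = (int(self.tile_shape[0]), int(self.tile_shape[1]))
        if min(self.tile_shape) < 1:
            raise ValueError("tile_shape must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape[:2]

    def channel(self, role: str) -> np.ndarray:
        return self.data[..., CHANNEL_ROLES.index(role)]


@dataclass
class ContrastLimits:
    """Per-channel (low_tail, high_tail) quantile saturation fractions.

    ``low_tail`` of the pixels saturate to 0 and ``high_tail`` to 1 after
    the linear stretch; both lie in [0, 1) with ``low + high < 1``.
    """

    cars: tuple[float, float] = DEFAULT_CONTRAST["CARS"]
    tpef: tuple[float, float] = DEFAULT_CONTRAST["TPEF"]
    shg: tuple[float, float] = DEFAULT_CONTRAST["SHG"]

    def __post_init__(self) -> None:
        for name, (lo, hi) in zip(CHANNEL_ROLES, self.as_tuple()):
            if not (0 <= lo < 1 and 0 <= hi < 1 and lo + hi < 1):
                raise ValueError(
                    f"invalid saturation fractions for {name}: ({lo}, {hi})"
                )

    def as_tuple(self):
        return (self.cars, self.tpef, self.shg)


def median_denoise(img: MultimodalImage, radius: int = 1) -> MultimodalImage:
    """Median-filter each channel with a square window of side 2*radius+1.

    Edges are handled by reflection.
    """
    if radius < 1:
        raise ValueError("radius must be >= 1")
    size = 2 * int(radius) + 1
    out = np.empty_like(img.data)
    for c in range(3):
        out[..., c] = ndimage.median_filter(img.data[..., c], size=size, mode="reflect")
    return replace(img, data=out, provenance=img.provenance + f"|median(r={radius})")


def downsample(img: MultimodalImage, factor: int = 4) -> MultimodalImage:
    """Block-mean downsampling by an integer factor (default 4).

    If the image dimensions are not divisible by ``factor`` the image is
    cropped to the largest divisible extent (logged).  The tile metadata
    is scaled accordingly.
    """
    factor = int(factor)
    if factor <= 0:
        raise ValueError("factor must be a positive integer")
    if factor == 1:
        return replace(img, provenance=img.provenance + "|downsample(1)")
    h, w = img.shape
    h2, w2 = (h // factor) * factor, (w // factor) * factor
    data = img.data
    if (h2, w2) != (h, w):
        logger.info("downsample: cropping %s -> %s for divisibility", (h, w), (h2, w2))
        data = data[:h2, :w2]
    out = data.reshape(h2 // factor, factor, w2 // factor, factor, 3).mean(axis=(1, 3))
    tile = (max(1, img.tile_shape[0] // factor), max(1, img.tile_shape[1] // factor))
    px = img.pixel_size * factor if img.pixel_size is not None else None
    return MultimodalImage(
        out, tile, px, img.provenance + f"|downsample({factor})"
    )


def correct_tile_illumination(
    img: MultimodalImage, eps: float = 0.3, method: str = "shared-profile"
) -> MultimodalImage:
    """Remove the uneven illumination of the individual tile scans.

    Two retrospective (calibration-free) estimators are available; both
    are deterministic, remove tile-to-tile gain steps as well as the
    within-tile vignette, and leave a flat (uniform) image unchanged.

    ``"shared-profile"`` (default) exploits the fact that the optical
    vignette is the same in every tile: the per-channel profile is the
    Gaussian-blurred (sigma = tile side / 4) average of mean-normalized
    tiles, so tile content averages out of the estimate.  Each tile is
    divided by the unit-mean profile and by a robust per-tile gain (its
    upper-decile brightness relative to the channel's, clamped to
    [0.5, 2] so nearly-empty tiles are not amplified).

    ``"tile-blur"`` estimates the field per tile as a heavy Gaussian
    blur (sigma = tile side / 4) of the tile itself, floored at ``eps``
    times the channel-wide field median — without the floor, near-empty
    (dark) areas would be divided by their own small blur value and
    amplified to tissue brightness — then divides it out and rescales by
    the channel's mean illumination level.  It needs no repeated tiles
    but leaks image content at scales above sigma into the field.
    """
    th, tw = img.tile_shape
    h, w = img.shape
    if h % th or w % tw:
        raise ValueError(
            f"tile shape {img.tile_shape} does not divide image shape {(h, w)}"
        )
    if method not in ("shared-profile", "tile-blur"):
        raise ValueError(f"unknown method {method!r}")
    sigma = min(th, tw) / 4.0
    ncols = w // tw
    out = np.empty_like(img.data)
    for c in range(3):
        chan = img.data[..., c]
        tiles = (
            chan.reshape(h // th, th, ncols, tw).transpose(0, 2, 1, 3).reshape(-1, th, tw)
        )
        if method == "shared-profile":
            means = np.maximum(tiles.mean(axis=(1, 2)), np.finfo(float).tiny)
            profile = ndimage.gaussian_filter(
                (tiles / means[:, None, None]).mean(axis=0), sigma, mode="reflect"
            )
            profile = np.maximum(profile, np.finfo(float).tiny)
            profile /= profile.mean()
            ref = max(np.quantile(chan, 0.9), np.finfo(float).tiny)
            for idx in range(tiles.shape[0]):
                i, j = divmod(idx, ncols)
                t = tiles[idx] / profile
                gain = float(np.clip(np.quantile(t, 0.9) / ref, 0.5, 2.0))
                out[i * th : (i + 1) * th, j * tw : (j + 1) * tw, c] = t / gain
        else:
            field = np.empty_like(chan)
            for idx in range(tiles.shape[0]):
                i, j = divmod(idx, ncols)
                field[i * th : (i + 1) * th, j * tw : (j + 1) * tw] = (
                    ndimage.gaussian_filter(tiles[idx], sigma, mode="reflect")
                )
            level = float(field.mean())
            floor = eps * max(float(np.median(field)), np.finfo(float).tiny)
            out[..., c] = chan / np.maximum(field, floor) * level
    return replace(img, data=out, provenance=img.provenance + f"|illumination({method})")


def adjust_contrast(
    img: MultimodalImage, limits: ContrastLimits | None = None
) -> MultimodalImage:
    """Quantile-clip and linearly rescale each channel to [0, 1].

    Intensities below the ``low_tail`` quantile map to 0, above the
    ``1 - high_tail`` quantile to 1.  A degenerate channel (equal
    quantiles) maps to all zeros with a warning.
    """
    limits = limits or ContrastLimits()
    out = np.empty_like(img.data)
    for c, (lo_f, hi_f) in enumerate(limits.as_tuple()):
        chan = img.data[..., c]
        lo = np.quantile(chan, lo_f)
        hi = np.quantile(chan, 1.0 - hi_f)
        if hi <= lo:
            warnings.warn(
                f"degenerate {CHANNEL_ROLES[c]} channel: quantiles coincide; "
                "mapping to 0",
                stacklevel=2,
            )
            out[..., c] = 0.0
        else:
            out[..., c] = np.clip((chan - lo) / (hi - lo), 0.0, 1.0)
    return replace(img, data=out, provenance=img.provenance + "|contrast")


def preprocess(
    img: MultimodalImage,
    median_radius: int = 1,
    factor: int = 4,
    limits: ContrastLimits | None = None,
) -> MultimodalImage:
    """Full fixed-order preprocessing chain.

    median filter -> block-mean downsampling -> per-tile illumination
    correction -> per-channel contrast stretch.  Deterministic.
    """
    img = median_denoise(img, median_radius)
    img = downsample(img, factor)
    img = correct_tile_illumination(img)
    return adjust_contrast(img, limits)
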