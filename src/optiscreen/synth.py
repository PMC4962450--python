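"""Synthetic scenes and cohorts with known ground truth.

Two generators make every downstream stage testable without instrument
data:

* :func:`generate_multimodal_pair` builds a tiled three-channel
  (CARS/TPEF/SHG) tissue scene together with a reference H&E image that
  is, by construction, a fixed affine color map of the clean channels —
  plus dark-violet nuclei and white background.  Nuclei appear as
  negative contrast (multiplicative darkening) in all three channels;
  each tile carries a multiplicative vignette and gain.

* :func:`generate_raman_cohort` builds a cohort of hyperspectral maps in
  which each pixel's spectrum is a sum of class-dependent Gaussian bands
  at fixed biological marker positions (785 cm^-1 DNA phosphate backbone;
  1003, 1449, 1657 cm^-1 protein bands), a smooth fluorescence-like
  baseline, per-individual random band-amplitude effects, and white
  noise.

Both are bit-reproducible for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy import ndimage

from .mm_preprocess import MultimodalImage
from .raman_preprocess import RamanMap

#: dark-violet used for nuclei in the reference H&E rendering
NUCLEI_COLOR = (0.29, 0.13, 0.37)

#: fixed affine map from (CARS, TPEF, SHG) to reference H&E RGB:
#: rgb = HE_OFFSET + channels @ HE_MATRIX.T  (clipped to [0, 1])
HE_OFFSET = np.array([0.97, 0.85, 0.90])
HE_MATRIX = np.array(
    [
        [-0.22, -0.38, -0.06],  # R
        [-0.10, -0.62, -0.18],  # G
        [-0.08, -0.40, -0.30],  # B
    ]
)

TISSUE_CLASSES = ("normal", "adenoma", "carcinoma")
EXCLUDED_CLASSES = ("muscle", "background")
ALL_CLASSES = TISSUE_CLASSES + EXCLUDED_CLASSES

#: Raman marker band positions (cm^-1)
BAND_CENTERS = (785.0, 1003.0, 1449.0, 1657.0)

#: per-class band amplitudes (arbitrary units).  785 cm^-1 (DNA) rises
#: along the adenoma-carcinoma sequence; protein bands shift modestly;
#: muscle is protein-heavy; background carries essentially no signal.
DEFAULT_BAND_AMPLITUDES: dict[str, dict[float, float]] = {
    "normal": {785.0: 0.35, 1003.0: 0.55, 1449.0: 0.75, 1657.0: 0.85},
    "adenoma": {785.0: 0.65, 1003.0: 0.80, 1449.0: 0.60, 1657.0: 0.70},
    "carcinoma": {785.0: 0.95, 1003.0: 0.45, 1449.0: 0.50, 1657.0: 0.95},
    "muscle": {785.0: 0.20, 1003.0: 0.60, 1449.0: 1.05, 1657.0: 1.10},
    "background": {785.0: 0.0, 1003.0: 0.0, 1449.0: 0.0, 1657.0: 0.02},
}


# --------------------------------------------------------------------------
# multimodal / H&E image scenes
# --------------------------------------------------------------------------


@dataclass
class ImageSceneParams:
    """Configuration of one synthetic tiled tissue scene."""

    image_shape: tuple[int, int] = (512, 512)
    tile_shape: tuple[int, int] = (256, 256)
    n_nuclei: int = 120
    nuclei_radius_range: tuple[float, float] = (14.0, 22.0)
    lipid_blob_density: float = 0.10
    fiber_density: float = 0.06
    background_fraction: float = 0.30
    vignetting_strength: float = 0.30
    noise_sd: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        h, w = self.image_shape
        th, tw = self.tile_shape
        if h % th or w % tw:
            raise ValueError(
                f"image shape {self.image_shape} not divisible by tile shape "
                f"{self.tile_shape}"
            )
        for name in ("lipid_blob_density", "fiber_density", "background_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not 0.0 <= self.vignetting_strength < 1.0:
            raise ValueError("vignetting_strength must be in [0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n_nuclei < 0:
            raise ValueError("n_nuclei must be >= 0")


@dataclass
class ImageSceneTruth:
    """Generated scene plus every ground-truth layer."""

    multimodal: MultimodalImage  # observed: vignetted + noisy
    he_reference: np.ndarray  # (H, W, 3) RGB in [0, 1]
    nuclei_mask: np.ndarray  # bool
    background_mask: np.ndarray  # bool
    illumination_field: np.ndarray  # (H, W) multiplicative
    clean_multimodal: np.ndarray  # (H, W, 3), no vignette / noise


def _smooth_noise(rng: np.random.Generator, shape, sigma: float) -> np.ndarray:
    f = ndimage.gaussian_filter(rng.standard_normal(shape), sigma, mode="reflect")
    sd = f.std()
    return f / sd if sd > 0 else f


def _draw_disk(arr: np.ndarray, r0: float, c0: float, radius: float, value) -> None:
    h, w = arr.shape[:2]
    rlo, rhi = max(0, int(r0 - radius)), min(h, int(r0 + radius) + 1)
    clo, chi = max(0, int(c0 - radius)), min(w, int(c0 + radius) + 1)
    if rlo >= rhi or clo >= chi:
        return
    rr, cc = np.ogrid[rlo:rhi, clo:chi]
    inside = (rr - r0) ** 2 + (cc - c0) ** 2 <= radius**2
    arr[rlo:rhi, clo:chi][inside] = value


def render_he_reference(
    clean_multimodal: np.ndarray,
    nuclei_mask: np.ndarray,
    background_mask: np.ndarray,
    nuclei_color=NUCLEI_COLOR,
) -> np.ndarray:
    """Reference H&E: fixed affine color map of the clean channels,
    dark-violet nuclei, white background.  Deterministic in the truth
    layers, so a stored scene can be re-rendered exactly."""
    he = np.clip(HE_OFFSET + clean_multimodal @ HE_MATRIX.T, 0.0, 1.0)
    he[nuclei_mask] = nuclei_color
    he[background_mask] = 1.0
    return he


def _tile_illumination(
    rng: np.random.Generator, shape, tile_shape, strength: float
) -> np.ndarray:
    """Per-tile multiplicative field: random gain times a radial vignette.

    Identically 1 when strength is 0."""
    h, w = shape
    th, tw = tile_shape
    field = np.ones((h, w))
    rr = (np.arange(th) - (th - 1) / 2.0) / (th / 2.0)
    cc = (np.arange(tw) - (tw - 1) / 2.0) / (tw / 2.0)
    r2 = rr[:, None] ** 2 + cc[None, :] ** 2  # 0 centre .. ~2 corners
    for i in range(0, h, th):
        for j in range(0, w, tw):
            gain = 1.0 + strength * rng.uniform(-0.35, 0.35)
            field[i : i + th, j : j + tw] = gain * (1.0 - strength * 0.5 * (r2 / 2.0))
    return field


def generate_multimodal_pair(params: ImageSceneParams) -> ImageSceneTruth:
    """Generate one paired multimodal / reference-H&E scene.

    CARS shows bright lipid blobs over a dim matrix, TPEF diffuse
    cytoplasm signal, SHG filamentous fibers; nuclei darken all three
    channels multiplicatively (factor 0.2-0.5); the background region is
    nearly dark in every channel.
    """
    rng = np.random.default_rng(params.seed)
    h, w = params.image_shape

    # contiguous background region with the requested area fraction
    bg_field = _smooth_noise(rng, (h, w), min(h, w) / 8.0)
    if params.background_fraction > 0:
        thr = np.quantile(bg_field, params.background_fraction)
        background = bg_field < thr
    else:
        background = np.zeros((h, w), dtype=bool)
    foreground = ~background

    # TPEF: diffuse cytoplasm autofluorescence
    tpef = np.clip(0.60 + 0.12 * _smooth_noise(rng, (h, w), 12.0), 0.15, 1.0)

    # CARS: dim matrix plus bright lipid blobs
    cars = np.clip(0.18 + 0.05 * _smooth_noise(rng, (h, w), 8.0), 0.05, 1.0)
    blob_r = (4.0, 10.0)
    mean_blob_area = np.pi * ((blob_r[0] + blob_r[1]) / 2.0) ** 2
    n_blobs = int(params.lipid_blob_density * foreground.sum() / mean_blob_area)
    for _ in range(n_blobs):
        r0, c0 = rng.uniform(0, h), rng.uniform(0, w)
        _draw_disk(cars, r0, c0, rng.uniform(*blob_r), rng.uniform(0.75, 0.95))

    # SHG: filamentous collagen fibers as smoothed random walks
    shg = np.full((h, w), 0.06)
    n_fibers = int(params.fiber_density * h * w / 2500.0)
    fiber_canvas = np.zeros((h, w), dtype=bool)
    for _ in range(n_fibers):
        length = int(rng.uniform(0.2, 0.5) * min(h, w))
        pos = np.array([rng.uniform(0, h), rng.uniform(0, w)])
        ang = rng.uniform(0, 2 * np.pi)
        for _step in range(length):
            ang += rng.normal(0, 0.12)
            pos += np.array([np.sin(ang), np.cos(ang)])
            r0, c0 = int(pos[0]), int(pos[1])
            if 0 <= r0 < h and 0 <= c0 < w:
                fiber_canvas[r0, c0] = True
    fiber_canvas = ndimage.binary_dilation(fiber_canvas, iterations=1)
    shg[fiber_canvas] = 0.85
    shg = np.clip(ndimage.gaussian_filter(shg, 0.7), 0.0, 1.0)

    scene = np.stack([cars, tpef, shg], axis=-1)
    scene[background] *= 0.04  # nearly dark background in all channels

    # nuclei: multiplicative darkening in all channels
    nuclei = np.zeros((h, w), dtype=bool)
    darkening = np.ones((h, w))
    rmin, rmax = params.nuclei_radius_range
    placed = 0
    attempts = 0
    while placed < params.n_nuclei and attempts < 50 * max(params.n_nuclei, 1):
        attempts += 1
        r0, c0 = rng.uniform(0, h), rng.uniform(0, w)
        if background[min(int(r0), h - 1), min(int(c0), w - 1)]:
            continue
        radius = rng.uniform(rmin, rmax)
        factor = rng.uniform(0.2, 0.5)
        _draw_disk(nuclei, r0, c0, radius, True)
        _draw_disk(darkening, r0, c0, radius, factor)
        placed += 1
    nuclei &= foreground  # masks disjoint: background wins on overlap
    darkening[background] = 1.0
    scene *= darkening[..., None]
    scene = np.clip(scene, 0.0, 1.0)

    he = render_he_reference(scene, nuclei, background)

    field = _tile_illumination(
        rng, (h, w), params.tile_shape, params.vignetting_strength
    )
    observed = scene * field[..., None]
    if params.noise_sd > 0:
        observed = observed + params.noise_sd * rng.standard_normal(observed.shape)
    observed = np.clip(observed, 0.0, None)

    mm = MultimodalImage(observed, params.tile_shape, provenance="synthetic")
    return ImageSceneTruth(
        multimodal=mm,
        he_reference=he,
        nuclei_mask=nuclei,
        background_mask=background,
        illumination_field=field,
        clean_multimodal=scene,
    )


# --------------------------------------------------------------------------
# Raman hyperspectral cohorts
# --------------------------------------------------------------------------


def default_class_layout(
    rng: np.random.Generator, grid_shape: tuple[int, int], scan_index: int
) -> np.ndarray:
    """Contiguous-region label map for one scan.

    One primary tissue class (cycling normal -> adenoma -> carcinoma over
    scans) fills the scan; a background wedge occupies one corner
    (~15% of the area) and every other scan carries a muscle stripe
    along one edge (~10%), mimicking region-level annotation granularity.
    """
    rows, cols = grid_shape
    labels = np.full((rows, cols), TISSUE_CLASSES[scan_index % 3], dtype=object)
    # background corner wedge
    rr, cc = np.ogrid[:rows, :cols]
    corner = rng.integers(0, 4)
    r_edge = rr if corner in (0, 1) else rows - 1 - rr
    c_edge = cc if corner in (0, 2) else cols - 1 - cc
    extent = 0.55 * np.sqrt(rows * cols)
    labels[(r_edge + c_edge) < extent] = "background"
    if scan_index % 2 == 1:
        stripe = max(1, int(0.10 * rows))
        labels[-stripe:, :] = np.where(
            labels[-stripe:, :] == "background", "background", "muscle"
        )
    return labels


@dataclass
class RamanCohortParams:
    """Configuration of one synthetic Raman cohort.

    Defaults emulate the acquisition geometry of a small murine colon
    study: 6 individuals, ~6 scans each, 34x40-pixel maps (1360 spectra
    per scan) over a 600-1800 cm^-1 fingerprint axis sampled every
    2 cm^-1.
    """

    n_individuals: int = 6
    scans_per_individual: int = 6
    grid_shape: tuple[int, int] = (34, 40)
    wavenumber_axis: np.ndarray = field(
        default_factory=lambda: np.arange(600.0, 1801.0, 2.0)
    )
    class_band_amplitudes: dict[str, dict[float, float]] = field(
        default_factory=lambda: {
            c: dict(v) for c, v in DEFAULT_BAND_AMPLITUDES.items()
        }
    )
    band_width: float = 9.0  # Gaussian sigma, cm^-1
    baseline_order: int = 3
    baseline_scale: float = 0.8
    individual_effect_sd: float = 0.05
    noise_sd: float = 0.05
    class_region_layout: Callable = default_class_layout
    seed: int = 0

    def __post_init__(self) -> None:
        self.wavenumber_axis = np.asarray(self.wavenumber_axis, dtype=float)
        if np.any(np.diff(self.wavenumber_axis) <= 0):
            raise ValueError("wavenumber axis must be strictly increasing")
        if min(self.grid_shape) <= 0:
            raise ValueError("grid_shape must be positive")
        for cls, bands in self.class_band_amplitudes.items():
            if any(a < 0 for a in bands.values()):
                raise ValueError(f"negative band amplitude for class {cls!r}")
        if self.n_individuals < 1 or self.scans_per_individual < 1:
            raise ValueError("cohort must contain at least one scan")


@dataclass
class RamanCohort:
    """Generated maps plus per-pixel ground truth."""

    maps: list[RamanMap]
    truth_labels: list[np.ndarray]  # per-map, per-pixel class strings
    truth_baselines: list[np.ndarray]  # per-map (n_pixels, n_wavenumbers)
    params: RamanCohortParams


def generate_raman_cohort(params: RamanCohortParams) -> RamanCohort:
    """Generate a cohort of labelled hyperspectral maps.

    Each spectrum is sum over bands of amplitude(class, individual) times
    a Gaussian line, plus a smooth polynomial-with-hump baseline scaled
    per pixel, plus white noise.  Per-individual effects are drawn once
    per (individual, band) as 1 + N(0, individual_effect_sd)
    multiplicative factors, shared across that individual's scans.
    """
    classes = list(params.class_band_amplitudes)
    if len(classes) < 2:
        raise ValueError("need at least two classes")
    rng = np.random.default_rng(params.seed)
    wn = params.wavenumber_axis
    centers = sorted({c for bands in params.class_band_amplitudes.values() for c in bands})
    lines = np.stack(
        [np.exp(-0.5 * ((wn - c) / params.band_width) ** 2) for c in centers]
    )  # (n_bands, n_wn)
    amp = np.array(
        [[params.class_band_amplitudes[cls].get(c, 0.0) for c in centers] for cls in classes]
    )  # (n_classes, n_bands)

    # broad fluorescence hump shared across the cohort
    hump = np.exp(-0.5 * ((wn - 1050.0) / 320.0) ** 2)
    t = np.linspace(-1.0, 1.0, wn.size)

    maps: list[RamanMap] = []
    truth_labels: list[np.ndarray] = []
    truth_baselines: list[np.ndarray] = []
    rows, cols = params.grid_shape
    n_px = rows * cols
    for ind in range(params.n_individuals):
        ind_id = f"ind{ind:02d}"
        # per-(individual, band) multiplicative amplitude effects
        ind_eff = 1.0 + params.individual_effect_sd * rng.standard_normal(len(centers))
        ind_amp = amp * ind_eff[None, :]
        for scan in range(params.scans_per_individual):
            scan_id = f"scan{scan:02d}"
            layout = params.class_region_layout(rng, params.grid_shape, scan)
            labels = np.asarray(layout, dtype=object).ravel()
            cls_idx = np.array([classes.index(c) for c in labels])
            signal = ind_amp[cls_idx] @ lines  # (n_px, n_wn)

            # smooth per-scan baseline with per-pixel intensity jitter
            coeffs = rng.uniform(-0.3, 0.3, params.baseline_order + 1)
            poly = np.polynomial.polynomial.polyval(t, coeffs)
            shape_curve = params.baseline_scale * (
                0.6 + 0.4 * hump + poly - poly.min()
            )
            px_scale = 1.0 + 0.2 * rng.random(n_px)
            baseline = px_scale[:, None] * shape_curve[None, :]

            spectra = signal + baseline
            if params.noise_sd > 0:
                spectra = spectra + params.noise_sd * rng.standard_normal(spectra.shape)
            maps.append(
                RamanMap(
                    spectra=spectra,
                    wavenumbers=wn,
                    grid_shape=params.grid_shape,
                    individual_id=ind_id,
                    scan_id=scan_id,
                    pixel_labels=labels.copy(),
                )
            )
            truth_labels.append(labels)
            truth_baselines.append(baseline)
    return RamanCohort(
        maps=maps,
        truth_labels=truth_labels,
        truth_baselines=truth_baselines,
        params=params,
    )
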