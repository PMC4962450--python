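"""End-to-end orchestration of both screening pipelines.

``run_pipeline`` executes the requested stages on synthetic (or loaded)
data with one master seed, writes artifacts, and returns a JSON-ready
report.  Per-stage seeds derive from the master seed by a fixed counter
scheme so stages stay independently reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
from pydantic import BaseModel, ConfigDict
from scipy import ndimage
from skimage.morphology import disk

from . import io as osio
from .mm_preprocess import ContrastLimits, preprocess
from .pseudo_he import (
    compose_pseudo_he,
    estimate_background_weight,
    fit_color_model,
    fit_nuclei_model,
    predict_color,
    predict_nuclei_mask,
    save_models,
)
from .raman_preprocess import (
    choose_n_components,
    fit_pca,
    preprocess_map,
    project_pca,
)
from .shp import (
    assemble_dataset,
    cluster_scan,
    individual_out_cv,
    majority_truth_mapping,
    transfer_annotation,
    wilcoxon_screen,
)
from .synth import (
    ImageSceneParams,
    RamanCohortParams,
    generate_multimodal_pair,
    generate_raman_cohort,
)

logger = logging.getLogger(__name__)


class ImagesConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    image_shape: tuple[int, int] = (512, 512)
    tile_shape: tuple[int, int] = (256, 256)
    n_nuclei: int = 120
    background_fraction: float = 0.30
    vignetting_strength: float = 0.30
    noise_sd: float = 0.02
    median_radius: int = 1
    downsample_factor: int = 4
    mean_radius: int = 7


class RamanConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    n_individuals: int = 6
    scans_per_individual: int = 6
    grid_shape: tuple[int, int] = (34, 40)
    noise_sd: float = 0.05
    individual_effect_sd: float = 0.05
    snip_iterations: int = 30
    crop_range: tuple[float, float] = (600.0, 1800.0)
    k_annotation: int = 9
    n_neighbors: int = 1
    minkowski_p: float = 2.0
    kernel: str = "optimal"
    level: str = "region"
    pca_variance: float = 0.99
    pca_cap: int = 20


class RunConfig(BaseModel):
    """Schema-validated run configuration; unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")

    seed: int = 0
    stages: list[str] = ["images", "raman"]
    images: ImagesConfig = ImagesConfig()
    raman: RamanConfig = RamanConfig()


def stage_seed(master_seed: int, stage_index: int) -> int:
    """Fixed counter scheme deriving a per-stage seed below 2**31."""
    return (master_seed * 1009 + 101 * stage_index + 7) % (2**31)


def config_hash(config: RunConfig) -> str:
    return hashlib.sha256(
        json.dumps(config.model_dump(), sort_keys=True).encode()
    ).hexdigest()[:16]


def block_mean(arr: np.ndarray, factor: int) -> np.ndarray:
    """Block-mean downsampling of a 2-D (or 2-D + channel) array."""
    if factor == 1:
        return np.asarray(arr, dtype=float)
    a = np.asarray(arr, dtype=float)
    h, w = a.shape[:2]
    h2, w2 = (h // factor) * factor, (w // factor) * factor
    a = a[:h2, :w2]
    if a.ndim == 2:
        return a.reshape(h2 // factor, factor, w2 // factor, factor).mean(axis=(1, 3))
    return a.reshape(h2 // factor, factor, w2 // factor, factor, -1).mean(axis=(1, 3))


def iou(a: np.ndarray, b: np.ndarray) -> float:
    """Intersection-over-union of two boolean masks."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    union = np.logical_or(a, b).sum()
    if union == 0:
        return 1.0
    return float(np.logical_and(a, b).sum() / union)


def run_image_stage(cfg: ImagesConfig, seed: int, out_dir: Path | None = None) -> dict:
    """Synthetic scene -> preprocessing -> trained models -> pseudo-HE.

    Trains the color and nuclei models on the scene's own reference (the
    single-training-image workflow) and reports fidelity metrics against
    the generator's ground truth.
    """
    params = ImageSceneParams(
        image_shape=cfg.image_shape,
        tile_shape=cfg.tile_shape,
        n_nuclei=cfg.n_nuclei,
        background_fraction=cfg.background_fraction,
        vignetting_strength=cfg.vignetting_strength,
        noise_sd=cfg.noise_sd,
        seed=seed,
    )
    truth = generate_multimodal_pair(params)
    pre = preprocess(
        truth.multimodal, cfg.median_radius, cfg.downsample_factor, ContrastLimits()
    )
    f = cfg.downsample_factor
    he_ds = block_mean(truth.he_reference, f)
    nuc_frac = block_mean(truth.nuclei_mask.astype(float), f)
    bg_frac = block_mean(truth.background_mask.astype(float), f)
    nuc_ds = nuc_frac > 0.5
    bg_ds = bg_frac > 0.5

    pure_tissue = (bg_frac == 0) & (nuc_frac == 0)
    color_model = fit_color_model(pre, he_ds, n_components=3, mask=pure_tissue)
    fg = ~bg_ds
    nuclei_model = fit_nuclei_model(pre.data[fg], nuc_ds[fg])

    weight = estimate_background_weight(pre, mean_radius=cfg.mean_radius, seed=seed)
    nuclei_pred = predict_nuclei_mask(nuclei_model, pre, exclude=weight > 0.5)
    color = predict_color(color_model, pre)
    pseudo = compose_pseudo_he(color, nuclei_pred, weight)

    # fidelity in strict non-nuclei foreground: the weighting mask
    # deliberately feathers tissue edges toward white, so erode by the
    # mean-filter radius before comparing colors
    strict_fg = ndimage.binary_erosion(~bg_ds, structure=disk(cfg.mean_radius)) & (
        nuc_frac == 0
    )
    # tiny demo scenes can erode away entirely; report NaN rather than warn
    if strict_fg.any():
        mae = float(np.abs(pseudo[strict_fg] - he_ds[strict_fg]).mean())
    else:
        mae = float("nan")
    metrics = {
        "color_mae_foreground": mae,
        "background_iou": iou(weight > 0.5, bg_ds),
        "nuclei_iou": iou(nuclei_pred, nuc_ds),
        "pls_training_rmse": color_model.training_rmse,
        "n_foreground_pixels": int(strict_fg.sum()),
    }
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
        osio.save_multimodal_tiff(out_dir / "multimodal.tif", truth.multimodal)
        osio.save_rgb_tiff(out_dir / "he_reference.tif", truth.he_reference)
        osio.save_rgb_tiff(out_dir / "pseudo_he.tif", pseudo)
        osio.save_mask_tiff(out_dir / "background_weight.tif", weight)
        osio.save_mask_tiff(out_dir / "nuclei_mask.tif", nuclei_pred)
        save_models(out_dir / "models.json", color_model, nuclei_model)
    return metrics


def prepare_shp_dataset(cfg: RamanConfig, seed: int):
    """Synthetic cohort -> pre-treatment -> PCA -> annotation transfer.

    The simulated pathologist maps each per-scan k-means cluster to the
    majority ground-truth class of its pixels.  Returns the
    classification-ready dataset, the cohort and the component count.
    """
    params = RamanCohortParams(
        n_individuals=cfg.n_individuals,
        scans_per_individual=cfg.scans_per_individual,
        grid_shape=cfg.grid_shape,
        noise_sd=cfg.noise_sd,
        individual_effect_sd=cfg.individual_effect_sd,
        seed=seed,
    )
    cohort = generate_raman_cohort(params)
    pre_maps = [
        preprocess_map(m, cfg.snip_iterations, cfg.crop_range) for m in cohort.maps
    ]
    all_valid = np.vstack([m.spectra[m.valid] for m in pre_maps])
    n_comp = choose_n_components(all_valid, cfg.pca_variance, cfg.pca_cap)
    pca = fit_pca(all_valid, n_comp)

    score_blocks, label_blocks, inds, scans = [], [], [], []
    for m, truth_lab in zip(pre_maps, cohort.truth_labels):
        scores = project_pca(pca, m.spectra[m.valid])
        truth_v = truth_lab[m.valid]
        clusters = cluster_scan(scores, k=min(cfg.k_annotation, scores.shape[0]), seed=seed)
        mapping = majority_truth_mapping(clusters, truth_v)
        transferred = transfer_annotation(clusters, mapping)
        score_blocks.append(scores)
        label_blocks.append(transferred)
        inds.append(m.individual_id)
        scans.append(m.scan_id)
    dataset = assemble_dataset(score_blocks, label_blocks, inds, scans)
    return dataset, cohort, n_comp


def run_raman_stage(cfg: RamanConfig, seed: int, out_dir: Path | None = None) -> dict:
    """Full spectral-histopathology stage: dataset assembly plus KKNN
    individual-out cross-validation and the univariate PC screen."""
    dataset, cohort, n_comp = prepare_shp_dataset(cfg, seed)
    report = individual_out_cv(
        dataset,
        k=cfg.n_neighbors,
        p=cfg.minkowski_p,
        kernel=cfg.kernel,
        level=cfg.level,
    )

    # univariate screen: normal vs tumor on PC scores 3-5
    tumor = np.isin(dataset.labels.astype(str), ["adenoma", "carcinoma"])
    screen_groups = np.where(tumor, "tumor", "normal")
    comps = [c for c in (3, 4, 5) if c <= dataset.features.shape[1]]
    pvals = wilcoxon_screen(dataset.features, screen_groups, comps) if comps else {}

    result = {
        "n_components": n_comp,
        "n_spectra_retained": int(dataset.labels.shape[0]),
        "cv": report.to_dict(),
        "wilcoxon_normal_vs_tumor": {str(c): p for c, p in pvals.items()},
    }
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
        osio.save_raman_cohort(out_dir / "cohort.h5", cohort.maps)
    return result


def run_pipeline(config: RunConfig, out_dir=None) -> dict:
    """Execute the configured stages and return the JSON-ready report.

    Deterministic for a fixed config: the report (excluding wall-clock
    metadata, which is deliberately omitted) is bit-reproducible.
    """
    out_dir = Path(out_dir) if out_dir is not None else None
    report = {
        "config": config.model_dump(),
        "config_hash": config_hash(config),
        "seed": config.seed,
        "stages": {},
    }
    for name in config.stages:
        if name == "images":
            logger.info("running image stage")
            report["stages"]["images"] = run_image_stage(
                config.images,
                stage_seed(config.seed, 0),
                out_dir / "images" if out_dir else None,
            )
        elif name == "raman":
            logger.info("running raman stage")
            report["stages"]["raman"] = run_raman_stage(
                config.raman,
                stage_seed(config.seed, 1),
                out_dir / "raman" if out_dir else None,
            )
        else:
            raise ValueError(f"unknown stage {name!r}")
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
        with open(out_dir / "report.json", "w") as fh:
            json.dump(report, fh, indent=2)
    return report


def load_config(path) -> RunConfig:
    """Load and validate a YAML/JSON run configuration."""
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return RunConfig.model_validate(raw)
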