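"""Readers and writers for the standard on-disk formats.

Multimodal images travel as TIFF (one file per channel or a single
3-plane stack), masks as 8-bit TIFF/PNG, Raman maps and cohorts as HDF5
with datasets ``spectra`` (n_pixels x n_wavenumbers), ``wavenumbers``,
``grid_shape`` and optional ``labels``, plus ``individual_id`` /
``scan_id`` attributes.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import tifffile

from .mm_preprocess import CHANNEL_ROLES, MultimodalImage
from .raman_preprocess import RamanMap


# --------------------------------------------------------------------------
# images
# --------------------------------------------------------------------------


def save_multimodal_tiff(path, img: MultimodalImage, per_channel: bool = False):
    """Write a multimodal image as float32 TIFF.

    ``per_channel=True`` writes one grayscale file per channel next to
    ``path`` (suffixing the channel role), otherwise a single
    3-sample-per-pixel file; tile shape is stored in the description.
    """
    path = Path(path)
    meta = json.dumps({"tile_shape": list(img.tile_shape), "channels": CHANNEL_ROLES})
    if per_channel:
        for c, role in enumerate(CHANNEL_ROLES):
            out = path.with_name(f"{path.stem}_{role}{path.suffix}")
            tifffile.imwrite(out, img.data[..., c].astype(np.float32), description=meta)
    else:
        tifffile.imwrite(
            path, img.data.astype(np.float32), description=meta, photometric="rgb"
        )


def load_multimodal_tiff(path, tile_shape=None) -> MultimodalImage:
    """Read a 3-channel TIFF written by :func:`save_multimodal_tiff`.

    Falls back to ``tile_shape`` (or the full image) when no metadata is
    embedded.
    """
    with tifffile.TiffFile(path) as tf:
        data = tf.asarray()
        desc = tf.pages[0].description
    if data.ndim == 3 and data.shape[0] == 3 and data.shape[-1] != 3:
        data = np.moveaxis(data, 0, -1)
    if tile_shape is None:
        try:
            tile_shape = tuple(json.loads(desc)["tile_shape"])
        except (json.JSONDecodeError, KeyError, TypeError):
            tile_shape = data.shape[:2]
    return MultimodalImage(np.asarray(data, dtype=float), tile_shape)


def save_rgb_tiff(path, rgb: np.ndarray) -> None:
    """Write an RGB image in [0, 1] as 8-bit TIFF."""
    arr = np.clip(np.asarray(rgb, dtype=float), 0.0, 1.0)
    tifffile.imwrite(path, (arr * 255.0 + 0.5).astype(np.uint8), photometric="rgb")


def save_mask_tiff(path, mask: np.ndarray) -> None:
    """Write a binary or [0,1] weight mask as 8-bit TIFF."""
    arr = np.clip(np.asarray(mask, dtype=float), 0.0, 1.0)
    tifffile.imwrite(path, (arr * 255.0 + 0.5).astype(np.uint8))


# --------------------------------------------------------------------------
# Raman maps / cohorts
# --------------------------------------------------------------------------


def _write_map(group: h5py.Group, rmap: RamanMap) -> None:
    group.create_dataset("spectra", data=rmap.spectra)
    group.create_dataset("wavenumbers", data=rmap.wavenumbers)
    group.create_dataset("grid_shape", data=np.asarray(rmap.grid_shape))
    if rmap.pixel_labels is not None:
        group.create_dataset(
            "labels", data=np.asarray(rmap.pixel_labels, dtype="S32")
        )
    if rmap.valid is not None:
        group.create_dataset("valid", data=np.asarray(rmap.valid, dtype=bool))
    group.attrs["individual_id"] = rmap.individual_id
    group.attrs["scan_id"] = rmap.scan_id


def _read_map(group: h5py.Group) -> RamanMap:
    labels = None
    if "labels" in group:
        labels = np.array([s.decode() for s in group["labels"][()]], dtype=object)
    valid = group["valid"][()] if "valid" in group else None
    return RamanMap(
        spectra=group["spectra"][()],
        wavenumbers=group["wavenumbers"][()],
        grid_shape=tuple(group["grid_shape"][()]),
        individual_id=str(group.attrs["individual_id"]),
        scan_id=str(group.attrs["scan_id"]),
        pixel_labels=labels,
        valid=valid,
    )


def save_raman_map(path, rmap: RamanMap) -> None:
    with h5py.File(path, "w") as fh:
        _write_map(fh, rmap)


def load_raman_map(path) -> RamanMap:
    with h5py.File(path, "r") as fh:
        return _read_map(fh)


def save_raman_cohort(path, maps: list[RamanMap]) -> None:
    """Write a cohort as one HDF5 group per map (``map000``, ...)."""
    with h5py.File(path, "w") as fh:
        for i, rmap in enumerate(maps):
            _write_map(fh.create_group(f"map{i:03d}"), rmap)


def load_raman_cohort(path) -> list[RamanMap]:
    with h5py.File(path, "r") as fh:
        return [_read_map(fh[name]) for name in sorted(fh.keys())]
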