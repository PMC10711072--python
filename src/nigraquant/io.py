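"""NIfTI / CSV / YAML I/O helpers."""

from __future__ import annotations

from pathlib import Path
from typing import Union

import nibabel as nib
import numpy as np
import yaml

from .datatypes import MaskSet, VolumeImage

PathLike = Union[str, Path]


def _affine(voxel_dims) -> np.ndarray:
    """RAS-aligned affine with the given voxel dimensions (mm)."""
    return np.diag([voxel_dims[0], voxel_dims[1], voxel_dims[2], 1.0])


def save_volume(volume: VolumeImage, path: PathLike) -> None:
    img = nib.Nifti1Image(volume.data.astype(np.float32),
                          _affine(volume.voxel_dims))
    nib.save(img, str(path))


def load_volume(path: PathLike, modality: str) -> VolumeImage:
    img = nib.load(str(path))
    voxel_dims = tuple(float(z) for z in img.header.get_zooms()[:3])
    return VolumeImage(np.asanyarray(img.dataobj, dtype=np.float64),
                       voxel_dims, modality)


def save_mask(mask: np.ndarray, voxel_dims, path: PathLike) -> None:
    img = nib.Nifti1Image(np.asarray(mask, dtype=np.uint8),
                          _affine(voxel_dims))
    nib.save(img, str(path))


def load_mask(path: PathLike) -> np.ndarray:
    img = nib.load(str(path))
    return np.asanyarray(img.dataobj) > 0


def load_mask_set(sn_path: PathLike, bg_path: PathLike) -> MaskSet:
    """MaskSet from SN and background label images (shared grid).

    The analysis slices are inferred from the SN mask occupancy.
    """
    sn = load_mask(sn_path)
    bg = load_mask(bg_path)
    slices = tuple(int(z) for z in np.flatnonzero(sn.any(axis=(0, 1))))
    if len(slices) != 3:
        raise ValueError(
            f"expected an SN mask on exactly 3 slices, found {len(slices)}")
    return MaskSet(sn_mask=sn, background_mask=bg, analysis_slices=slices)


def load_yaml(path: PathLike) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def dump_yaml(obj: dict, path: PathLike) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(obj, fh, sort_keys=False)
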