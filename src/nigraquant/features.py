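"""Quantitative SN-mask parameter extraction.

Implements the nine mask parameters reported per subject: for the
neuromelanin-sensitive volume the mean signal, the 90th/10th-percentile
contrast range, the mask area and the area surviving a high-signal
threshold; for QSM the mean susceptibility, mask area and the area of
iron-poor voxels (chi below the cutoff); for SMWI (synthesised here from
QSM and the SWI magnitude) the mean signal, mask area and low-signal area.
Areas are in-plane voxel areas summed over both hemispheres and the three
analysis slices, in mm^2.
"""

from __future__ import annotations

import warnings
from typing import Mapping, Optional, Sequence

import numpy as np

from .datatypes import (DegenerateMaskError, FeatureVector, GeometryError,
                        MaskSet, ThresholdPolicy, VolumeImage)

__all__ = [
    "mask_area", "mean_intensity_in_mask", "contrast_range",
    "nm_high_signal_threshold", "thresholded_area", "compute_smwi",
    "extract_feature_vector",
]


def _in_mask(volume: VolumeImage, mask: np.ndarray) -> np.ndarray:
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != volume.data.shape:
        raise GeometryError("mask and volume grids differ")
    if not mask.any():
        raise DegenerateMaskError("empty mask")
    return volume.data[mask]


def mask_area(mask: np.ndarray, voxel_dims: Sequence[float]) -> float:
    """Mask area in mm^2: voxel count x in-plane voxel area.

    Both hemispheres and all analysis slices pool into a single area, the
    convention used for the reported mask sizes.
    """
    mask = np.asarray(mask, dtype=bool)
    n = int(mask.sum())
    if n == 0:
        raise DegenerateMaskError("empty mask")
    return n * float(voxel_dims[0] * voxel_dims[1])


def mean_intensity_in_mask(volume: VolumeImage, mask: np.ndarray) -> float:
    """Arithmetic mean of in-mask voxel values (a.u. or ppb)."""
    return float(np.mean(_in_mask(volume, mask)))


def contrast_range(volume: VolumeImage, mask: np.ndarray) -> float:
    """Ratio of the 90th to the 10th percentile of in-mask signal.

    Percentiles use linear interpolation between order statistics.  At
    least 10 in-mask voxels and a positive 10th percentile are required.
    """
    vals = _in_mask(volume, mask)
    if vals.size < 10:
        raise DegenerateMaskError(
            f"contrast range needs >= 10 voxels, got {vals.size}")
    p10, p90 = np.percentile(vals, [10.0, 90.0])
    if p10 <= 0:
        raise ValueError("contrast range undefined: 10th percentile <= 0")
    return float(p90 / p10)


def nm_high_signal_threshold(volume: VolumeImage, masks: MaskSet,
                             policy: ThresholdPolicy,
                             calibration: Optional[tuple] = None) -> float:
    """High-signal cutoff for the NM mask (a.u.).

    ``fixed`` mode: background mean + ``policy.nm_k`` x background SD --
    the standard normalisation of NM-MRI signal against an adjacent
    reference region.  ``auc_sweep`` mode: maximise the group-separation
    AUC of the resulting thresholded area over a cutoff grid, given
    ``calibration = (list of (volume, masks), labels)`` for a labelled
    cohort; ties prefer the higher (more specific) cutoff.
    """
    bg = _in_mask(volume, masks.background_mask)
    if policy.optimization_mode == "fixed":
        mean, sd = float(bg.mean()), float(bg.std())
        if sd == 0:
            warnings.warn("zero background variance; cutoff = background mean")
            return mean
        return mean + policy.nm_k * sd
    if calibration is None:
        raise ValueError("auc_sweep mode needs a labelled calibration cohort")
    return _sweep_nm_threshold(calibration)


def _sweep_nm_threshold(calibration: tuple) -> float:
    from .stats import empirical_auc  # local import; stats depends on nothing here

    cohort, labels = calibration
    labels = np.asarray(labels)
    in_mask = [vol.data[m.sn_mask] for vol, m in cohort]
    pooled = np.concatenate(in_mask)
    grid = np.unique(np.percentile(pooled, np.linspace(2, 98, 49)))
    best = (-np.inf, None)
    for cutoff in grid:
        areas = np.array([float((v > cutoff).sum()) for v in in_mask])
        # Patients lose high-NM-signal area: lower area indicates disease.
        auc = empirical_auc(-areas, labels == "patient")
        if auc >= best[0]:  # ties -> later (higher) cutoff
            best = (auc, float(cutoff))
    return best[1]


def thresholded_area(volume: VolumeImage, mask: np.ndarray, cutoff: float,
                     direction: str, voxel_dims: Sequence[float]) -> float:
    """Area (mm^2) of in-mask voxels strictly above/below ``cutoff``.

    ``direction`` is ``"above"`` (NM high-signal rule) or ``"below"``
    (QSM low-chi and SMWI low-signal rules).  Always <= ``mask_area``.
    """
    vals = _in_mask(volume, mask)
    if direction == "above":
        n = int((vals > cutoff).sum())
    elif direction == "below":
        n = int((vals < cutoff).sum())
    else:
        raise ValueError(f"unknown direction {direction!r}")
    return n * float(voxel_dims[0] * voxel_dims[1])


def compute_smwi(qsm: VolumeImage, magnitude: VolumeImage,
                 chi_low: float = 70.0, chi_high: float = 170.0,
                 power: int = 4) -> VolumeImage:
    """Susceptibility map-weighted image from QSM and SWI magnitude.

    The susceptibility weight is 1 for chi <= ``chi_low``, 0 for chi >=
    ``chi_high`` and linear in between; the magnitude is multiplied by the
    weight raised to ``power``.  High-susceptibility (iron-rich) tissue is
    suppressed, sharpening nigral contrast.
    """
    if qsm.data.shape != magnitude.data.shape:
        raise GeometryError("QSM and magnitude grids differ")
    if qsm.voxel_dims != magnitude.voxel_dims:
        raise GeometryError("QSM and magnitude voxel dimensions differ")
    if not chi_low < chi_high:
        raise ValueError("chi_low must be below chi_high")
    if power < 1:
        raise ValueError("power must be >= 1")
    w = np.clip((chi_high - qsm.data) / (chi_high - chi_low), 0.0, 1.0)
    return VolumeImage(data=magnitude.data * w**power,
                       voxel_dims=magnitude.voxel_dims, modality="SMWI")


def extract_feature_vector(volumes: Mapping[str, VolumeImage],
                           masks: Mapping[str, MaskSet],
                           policy: Optional[ThresholdPolicy] = None
                           ) -> FeatureVector:
    """All nine SN-mask parameters for one subject.

    ``volumes`` holds ``"NM"`` and ``"QSM"`` plus either ``"SMWI"`` or a
    ``"SWI_MAG"`` magnitude from which SMWI is synthesised.  ``masks``
    holds one MaskSet per native grid (``"NM"`` and ``"QSM"``; the QSM
    masks serve QSM and SMWI, which share a grid).  The composite marker
    is left unset; it is computed downstream.
    """
    policy = policy or ThresholdPolicy()
    for key in ("NM", "QSM"):
        if key not in volumes:
            raise KeyError(f"missing {key} volume")
        if key not in masks:
            raise KeyError(f"missing {key} mask set")
    nm, qsm = volumes["NM"], volumes["QSM"]
    if "SMWI" in volumes:
        smwi = volumes["SMWI"]
    elif "SWI_MAG" in volumes:
        smwi = compute_smwi(qsm, volumes["SWI_MAG"], policy.smwi_chi_low,
                            policy.smwi_chi_high, policy.smwi_power)
    else:
        raise KeyError("need an SMWI volume or a SWI_MAG magnitude")
    nm_masks, iron_masks = masks["NM"], masks["QSM"]

    def tagged(modality, fn, *args):
        try:
            return fn(*args)
        except DegenerateMaskError as exc:
            raise DegenerateMaskError(f"[{modality}] {exc}") from exc

    nm_cutoff = tagged("NM", nm_high_signal_threshold, nm, nm_masks, policy)
    smwi_bg = tagged("SMWI", _in_mask, smwi, iron_masks.background_mask)
    smwi_cutoff = float(np.quantile(smwi_bg, policy.smwi_low_quantile))

    return FeatureVector(
        nm_signal=tagged("NM", mean_intensity_in_mask, nm, nm_masks.sn_mask),
        nm_contrast_range=tagged("NM", contrast_range, nm, nm_masks.sn_mask),
        nm_size=tagged("NM", mask_area, nm_masks.sn_mask, nm.voxel_dims),
        nm_size_high=tagged("NM", thresholded_area, nm, nm_masks.sn_mask,
                            nm_cutoff, "above", nm.voxel_dims),
        qsm_chi_mean=tagged("QSM", mean_intensity_in_mask, qsm,
                            iron_masks.sn_mask),
        qsm_size=tagged("QSM", mask_area, iron_masks.sn_mask, qsm.voxel_dims),
        qsm_size_low=tagged("QSM", thresholded_area, qsm, iron_masks.sn_mask,
                            policy.qsm_chi_cutoff, "below", qsm.voxel_dims),
        smwi_signal=tagged("SMWI", mean_intensity_in_mask, smwi,
                           iron_masks.sn_mask),
        smwi_size=tagged("SMWI", mask_area, iron_masks.sn_mask,
                         smwi.voxel_dims),
        smwi_size_lowsig=tagged("SMWI", thresholded_area, smwi,
                                iron_masks.sn_mask, smwi_cutoff, "below",
                                smwi.voxel_dims),
    )
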