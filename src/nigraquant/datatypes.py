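"""Core containers shared across the pipeline.

A subject contributes up to three native-space volumes (neuromelanin-sensitive
T1, QSM in ppb, and the SWI magnitude companion from which SMWI is derived),
per-modality mask sets restricted to three analysis slices, and a clinical
record.  Feature extraction condenses these into the nine quantitative
substantia-nigra mask parameters plus the downstream composite marker.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from typing import Optional

import numpy as np

#: Modalities understood by the pipeline.
MODALITIES = ("NM", "QSM", "SWI_MAG", "SMWI")

#: Stable column order for feature tables (mask-parameter order of the
#: quantitative report: NM block, QSM block, SMWI block).
FEATURE_COLUMNS = (
    "nm_signal",
    "nm_contrast_range",
    "nm_size",
    "nm_size_high",
    "qsm_chi_mean",
    "qsm_size",
    "qsm_size_low",
    "smwi_signal",
    "smwi_size",
    "smwi_size_lowsig",
)

CLINICAL_COLUMNS = ("age", "mmse", "updrs1", "updrs2", "updrs3")


class DegenerateMaskError(ValueError):
    """Raised when a mask is empty or otherwise unusable for ROI statistics."""


class GeometryError(ValueError):
    """Raised when volumes/masks do not share a common grid."""


@dataclass
class VolumeImage:
    """A 3D scalar image with voxel dimensions and a modality tag.

    ``data`` is indexed (x, y, z) with z the slice axis; ``voxel_dims`` are in
    millimetres.  Units are a.u. for NM/SWI_MAG/SMWI and ppb for QSM.
    """

    data: np.ndarray
    voxel_dims: tuple[float, float, float]
    modality: str

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D volume, got shape {self.data.shape}")
        if self.modality not in MODALITIES:
            raise ValueError(f"unknown modality {self.modality!r}")
        if any(d <= 0 for d in self.voxel_dims):
            raise ValueError("voxel dimensions must be positive")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume contains non-finite values")

    @property
    def inplane_area(self) -> float:
        """Area of one voxel in the acquisition plane (mm^2)."""
        return float(self.voxel_dims[0] * self.voxel_dims[1])


@dataclass
class MaskSet:
    """Bilateral SN mask plus a background ROI, confined to three slices."""

    sn_mask: np.ndarray
    background_mask: np.ndarray
    analysis_slices: tuple[int, int, int]

    def __post_init__(self) -> None:
        self.sn_mask = np.asarray(self.sn_mask, dtype=bool)
        self.background_mask = np.asarray(self.background_mask, dtype=bool)
        if self.sn_mask.shape != self.background_mask.shape:
            raise GeometryError("SN and background masks must share a grid")
        if not self.sn_mask.any():
            raise DegenerateMaskError("SN mask is empty")
        if not self.background_mask.any():
            raise DegenerateMaskError("background mask is empty")
        if np.any(self.sn_mask & self.background_mask):
            raise ValueError("SN and background masks overlap")
        occupied = np.flatnonzero(self.sn_mask.any(axis=(0, 1)))
        if not set(occupied).issubset(set(self.analysis_slices)):
            raise ValueError("SN mask voxels fall outside the analysis slices")


@dataclass
class FeatureVector:
    """The nine quantitative SN-mask parameters plus the composite marker.

    Sizes are mm^2 pooled over both hemispheres and the three analysis
    slices; signal units follow the source modality.  ``composite`` stays
    ``None`` until computed downstream.
    """

    nm_signal: float
    nm_contrast_range: float
    nm_size: float
    nm_size_high: float
    qsm_chi_mean: float
    qsm_size: float
    qsm_size_low: float
    smwi_signal: float
    smwi_size: float
    smwi_size_lowsig: float
    composite: Optional[float] = None

    def __post_init__(self) -> None:
        for name in ("nm_size", "nm_size_high", "qsm_size", "qsm_size_low",
                     "smwi_size", "smwi_size_lowsig"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.nm_size_high > self.nm_size + 1e-9:
            raise ValueError("thresholded NM size exceeds unthresholded size")
        if self.qsm_size_low > self.qsm_size + 1e-9:
            raise ValueError("thresholded QSM size exceeds unthresholded size")
        if self.smwi_size_lowsig > self.smwi_size + 1e-9:
            raise ValueError("thresholded SMWI size exceeds unthresholded size")

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    @classmethod
    def from_dict(cls, d: dict) -> "FeatureVector":
        names = {f.name for f in fields(cls)}
        return cls(**{k: v for k, v in d.items() if k in names})


@dataclass
class SubjectRecord:
    """Group label, demographics, and clinical scores for one subject."""

    subject_id: str
    group: str  # "control" | "patient"
    age: float
    sex: str  # "M" | "F"
    updrs1: float
    updrs2: float
    updrs3: float
    mmse: float
    hy: float
    ledd: Optional[float] = None  # mg/day; patients only
    latent_severity: Optional[float] = None  # synthetic-only driver

    def __post_init__(self) -> None:
        if self.group not in ("control", "patient"):
            raise ValueError(f"unknown group {self.group!r}")
        if not 0 <= self.mmse <= 30:
            raise ValueError("MMSE must lie in [0, 30]")
        if not 0 <= self.hy <= 5:
            raise ValueError("H&Y stage must lie in [0, 5]")
        if min(self.updrs1, self.updrs2, self.updrs3) < 0:
            raise ValueError("UPDRS scores must be nonnegative")
        if self.group == "control" and self.hy != 0:
            raise ValueError("controls must have H&Y stage 0")


@dataclass
class ThresholdPolicy:
    """Thresholding rules for the size-after-threshold parameters.

    * QSM: voxels with susceptibility below ``qsm_chi_cutoff`` (iron-poor
      tissue, the nigrosome surrogate) count towards the low-chi size.
    * NM: high-signal cutoff = background mean + ``nm_k`` x background SD in
      ``fixed`` mode, or an AUC-maximising sweep over a cutoff grid on a
      labelled calibration cohort in ``auc_sweep`` mode.
    * SMWI: low-signal cutoff = the ``smwi_low_quantile`` quantile of the
      background-mask SMWI signal.
    """

    qsm_chi_cutoff: float = 70.0  # ppb
    nm_k: float = 3.0
    smwi_low_quantile: float = 0.10
    optimization_mode: str = "fixed"  # "fixed" | "auc_sweep"
    # SMWI synthesis constants (linear susceptibility weighting).
    smwi_chi_low: float = 70.0  # ppb; weight 1 below
    smwi_chi_high: float = 170.0  # ppb; weight 0 above
    smwi_power: int = 4

    def __post_init__(self) -> None:
        if self.qsm_chi_cutoff <= 0:
            raise ValueError("qsm_chi_cutoff must be positive")
        if self.nm_k < 0:
            raise ValueError("nm_k must be nonnegative")
        if not 0 < self.smwi_low_quantile < 1:
            raise ValueError("smwi_low_quantile must lie in (0, 1)")
        if self.optimization_mode not in ("fixed", "auc_sweep"):
            raise ValueError(f"unknown optimization_mode {self.optimization_mode!r}")
        if not self.smwi_chi_low < self.smwi_chi_high:
            raise ValueError("smwi_chi_low must be below smwi_chi_high")
        if self.smwi_power < 1:
            raise ValueError("smwi_power must be >= 1")


@dataclass
class SyntheticSubjectBundle:
    """One simulated subject: record, truth features, optional volumes."""

    record: SubjectRecord
    truth_features: FeatureVector
    volumes: Optional[dict] = None  # modality -> VolumeImage
    masks: Optional[dict] = None  # "NM"/"QSM" -> MaskSet
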