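"""Reference space and cohort containers.

Every analysis stage operates on a single :class:`BrainSpace`: a voxel grid
with a brain mask, an integer parcellation (for regional aggregation), region
centroids in millimetres and a lateral-ventricle mask (the subventricular-zone
proxy). Lesion masks and clinical records are paired one-to-one in a
:class:`LesionCohort`.

Coordinate convention: voxel indices are 0-based; the world coordinate of a
voxel is ``origin + index * voxel_size`` (mm). Volumes are reported in cm^3
(voxel count x voxel volume / 1000); all distances are in mm.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("gliomap")

GRADES = ("GBM", "astrocytoma", "oligodendroglioma")
#: Grades pooled as lower-grade glioma (WHO II-III).
LGG_GRADES = ("astrocytoma", "oligodendroglioma")


class ValidationError(ValueError):
    """Raised when a container violates one of its structural invariants."""


@dataclass
class BrainSpace:
    """A common reference grid shared by all masks and maps.

    Parameters
    ----------
    dims : tuple of int
        Voxels per axis.
    voxel_size : tuple of float
        Voxel edge lengths in mm (anisotropy allowed).
    origin : tuple of float
        World-mm coordinate of voxel (0, 0, 0).
    brain_mask : ndarray of bool
        In-brain voxels.
    parcellation : ndarray of int
        Region labels, 0 = background, 1..R inside the brain mask.
    region_centroids : ndarray, shape (R, 3)
        Region centroids in world mm, row r-1 for label r.
    ventricle_mask : ndarray of bool
        Lateral-ventricle voxels (subset of the brain mask).
    """

    dims: tuple[int, int, int]
    voxel_size: tuple[float, float, float]
    origin: tuple[float, float, float]
    brain_mask: np.ndarray
    parcellation: np.ndarray
    region_centroids: np.ndarray
    ventricle_mask: np.ndarray

    def __post_init__(self) -> None:
        self.dims = tuple(int(d) for d in self.dims)
        self.voxel_size = tuple(float(v) for v in self.voxel_size)
        self.origin = tuple(float(v) for v in self.origin)
        self.brain_mask = np.asarray(self.brain_mask, dtype=bool)
        self.parcellation = np.asarray(self.parcellation)
        self.region_centroids = np.asarray(self.region_centroids, dtype=float)
        self.ventricle_mask = np.asarray(self.ventricle_mask, dtype=bool)
        self.validate()

    # -- derived quantities -------------------------------------------------
    @property
    def n_regions(self) -> int:
        return int(self.region_centroids.shape[0])

    @property
    def voxel_volume_cm3(self) -> float:
        return float(np.prod(self.voxel_size)) / 1000.0

    @property
    def affine(self) -> np.ndarray:
        """NIfTI affine mapping voxel indices to world mm."""
        aff = np.eye(4)
        aff[:3, :3] = np.diag(self.voxel_size)
        aff[:3, 3] = self.origin
        return aff

    def world_coordinates(self) -> np.ndarray:
        """World-mm coordinates of every voxel, shape ``dims + (3,)``."""
        idx = np.stack(
            np.meshgrid(*(np.arange(d) for d in self.dims), indexing="ij"), axis=-1
        )
        return np.asarray(self.origin) + idx * np.asarray(self.voxel_size)

    def volume_cm3(self, mask: np.ndarray) -> float:
        """Volume of a binary mask in cm^3."""
        return float(np.count_nonzero(mask)) * self.voxel_volume_cm3

    # -- invariants ---------------------------------------------------------
    def validate(self) -> None:
        if self.brain_mask.shape != self.dims:
            raise ValidationError(
                f"brain_mask shape {self.brain_mask.shape} != dims {self.dims}"
            )
        if self.parcellation.shape != self.dims:
            raise ValidationError("parcellation shape mismatch")
        if self.ventricle_mask.shape != self.dims:
            raise ValidationError("ventricle_mask shape mismatch")
        if np.any((self.parcellation != 0) & ~self.brain_mask):
            raise ValidationError("parcellation nonzero outside brain_mask")
        if np.any(self.ventricle_mask & ~self.brain_mask):
            raise ValidationError("ventricle_mask not contained in brain_mask")
        labels = np.unique(self.parcellation[self.parcellation > 0])
        r = self.region_centroids.shape[0]
        if r and not np.array_equal(labels, np.arange(1, r + 1)):
            raise ValidationError(
                f"expected labels 1..{r}, found {labels.size} distinct labels"
            )
        if not np.all(np.isfinite(self.region_centroids)):
            raise ValidationError("non-finite region centroid")
        lo = np.asarray(self.origin) - np.asarray(self.voxel_size)
        hi = np.asarray(self.origin) + np.asarray(self.dims) * np.asarray(self.voxel_size)
        if r and (np.any(self.region_centroids < lo) or np.any(self.region_centroids > hi)):
            raise ValidationError("region centroid outside the bounding box")


@dataclass
class ClinicalRecord:
    """One patient's clinical row (baseline-characteristics fields)."""

    patient_id: str
    age: float
    sex: str  # "male" / "female"
    kps: float  # Karnofsky Performance Status, 0-100
    grade: str  # GBM / astrocytoma / oligodendroglioma
    survival_time: float  # months
    event: int  # 1 died, 0 censored
    dataset_id: str = "D1"

    def __post_init__(self) -> None:
        if self.grade not in GRADES:
            raise ValidationError(f"unknown grade {self.grade!r}")
        if not np.isnan(self.kps) and not (0 <= self.kps <= 100):
            raise ValidationError(f"KPS {self.kps} outside [0, 100]")
        if not np.isnan(self.survival_time) and self.survival_time < 0:
            raise ValidationError("negative survival_time")

    @property
    def is_gbm(self) -> bool:
        return self.grade == "GBM"


@dataclass
class LesionCohort:
    """Aligned binary lesion masks and clinical records on one grid."""

    space: BrainSpace
    masks: list[np.ndarray]
    records: list[ClinicalRecord]
    flagged: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.masks = [np.asarray(m, dtype=bool) for m in self.masks]
        self.validate()

    def __len__(self) -> int:
        return len(self.masks)

    @property
    def patient_ids(self) -> list[str]:
        return [r.patient_id for r in self.records]

    def clinical_frame(self) -> pd.DataFrame:
        """Clinical records as a DataFrame indexed by patient_id."""
        df = pd.DataFrame([vars(r) for r in self.records])
        return df.set_index("patient_id")

    def mask_stack(self) -> np.ndarray:
        """Lesion indicators as a (n_patients, n_voxels) boolean array."""
        return np.stack([m.ravel() for m in self.masks])

    def subset(self, keep: np.ndarray | list[bool] | list[str]) -> "LesionCohort":
        """Sub-cohort by boolean vector or list of patient ids."""
        if len(keep) and isinstance(keep[0], str):
            wanted = set(keep)
            sel = [pid in wanted for pid in self.patient_ids]
        else:
            sel = list(np.asarray(keep, dtype=bool))
        masks = [m for m, s in zip(self.masks, sel) if s]
        records = [r for r, s in zip(self.records, sel) if s]
        if not masks:
            raise ValidationError("subset selects no patients")
        return LesionCohort(self.space, masks, records)

    def validate(self) -> None:
        if len(self.masks) != len(self.records):
            raise ValidationError("masks and records are not aligned")
        ids = self.patient_ids
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate patient_id(s): {dupes}")
        for rec, mask in zip(self.records, self.masks):
            if mask.shape != self.space.dims:
                raise ValidationError(
                    f"mask of {rec.patient_id} has shape {mask.shape}, "
                    f"space is {self.space.dims}"
                )
            if not mask.any():
                raise ValidationError(f"empty lesion mask for {rec.patient_id}")
            outside = int(np.count_nonzero(mask & ~self.space.brain_mask))
            if outside:
                raise ValidationError(
                    f"mask of {rec.patient_id} has {outside} voxel(s) outside brain_mask"
                )
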