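"""Tumor frequency maps, predilection masks, overlap metrics and parcellation.

The frequency map is the voxelwise proportion of patients whose lesion
covers each voxel (each patient contributes weight 1); the predilection mask
is the top fraction (default 10%) of nonzero-frequency voxels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .space import BrainSpace, LesionCohort, LGG_GRADES, ValidationError

logger = logging.getLogger("gliomap")


@dataclass
class FrequencyMap:
    space: BrainSpace
    values: np.ndarray  # in [0, 1], zero outside brain_mask
    n_patients: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.space.dims:
            raise ValidationError("frequency map shape mismatch")
        if np.any(self.values < 0) or np.any(self.values > 1):
            raise ValidationError("frequency outside [0, 1]")
        if np.any(self.values[~self.space.brain_mask] != 0):
            raise ValidationError("frequency nonzero outside brain_mask")
        counts = self.values * self.n_patients
        if np.abs(counts - np.round(counts)).max() > 1e-6:
            raise ValidationError("values * n_patients are not integral")


@dataclass
class PredilectionMask:
    space: BrainSpace
    mask: np.ndarray
    fraction_q: float
    source_map_id: str = ""


def _select_subset(cohort: LesionCohort, subset: str | None):
    if subset is None or subset == "all":
        return np.ones(len(cohort), dtype=bool)
    if subset == "LGG":
        return np.array([r.grade in LGG_GRADES for r in cohort.records])
    return np.array([r.grade == subset for r in cohort.records])


def build_frequency_map(cohort: LesionCohort, subset: str | None = None) -> FrequencyMap:
    """Voxelwise proportion of (subset) patients whose lesion covers each voxel.

    ``subset`` may be None/"all", "GBM", "LGG", or a specific grade label.
    """
    sel = _select_subset(cohort, subset)
    n = int(sel.sum())
    if n == 0:
        raise ValidationError(f"subset {subset!r} selects no patients")
    acc = np.zeros(cohort.space.dims, dtype=np.int64)
    for mask, s in zip(cohort.masks, sel):
        if s:
            acc += mask
    logger.info("frequency map over %d patients (subset=%s)", n, subset)
    return FrequencyMap(cohort.space, acc / n, n)


def top_fraction_mask(
    fmap: FrequencyMap, q: float = 0.10, base: str = "nonzero",
    source_map_id: str = "",
) -> PredilectionMask:
    """Predilection mask: the ceil(q*V) highest-frequency voxels among the V
    base voxels (default: voxels with frequency > 0), including all voxels
    tied with the cutoff value."""
    if not (0 < q <= 1):
        raise ValidationError("q must be in (0, 1]")
    if base == "nonzero":
        base_mask = fmap.values > 0
    elif base == "brain":
        base_mask = fmap.space.brain_mask
    else:
        raise ValidationError(f"unknown base {base!r}")
    v = int(base_mask.sum())
    if v < 10:
        raise ValidationError("need at least 10 base voxels")
    vals = fmap.values[base_mask]
    k = int(np.ceil(q * v))
    cutoff = np.sort(vals)[::-1][k - 1]
    mask = base_mask & (fmap.values >= cutoff)
    realized = mask.sum() / v
    if realized > q + 1e-12:
        logger.info("tie rule at cutoff %.6g: realized fraction %.4f > q=%.4f",
                    cutoff, realized, q)
    return PredilectionMask(fmap.space, mask, q, source_map_id)


def overlap_metrics(
    lesion: np.ndarray, target: np.ndarray, space: BrainSpace
) -> tuple[float, float]:
    """(overlap volume cm^3, overlap proportion of the lesion's own volume)."""
    lesion = np.asarray(lesion, dtype=bool)
    target = np.asarray(target, dtype=bool)
    if lesion.shape != target.shape or lesion.shape != space.dims:
        raise ValidationError("lesion/target not on the space grid")
    n_lesion = int(lesion.sum())
    if n_lesion == 0:
        raise ValidationError("empty lesion mask")
    inter = int((lesion & target).sum())
    return inter * space.voxel_volume_cm3, inter / n_lesion


def rank_by_overlap(
    cohort: LesionCohort, target: np.ndarray, metric: str = "volume",
    fraction: float = 0.20,
) -> pd.DataFrame:
    """Patients ordered by overlap with ``target`` (descending), with
    top/bottom fraction flags; ties broken by patient_id."""
    if metric not in ("volume", "proportion"):
        raise ValidationError("metric must be 'volume' or 'proportion'")
    if len(cohort) < 5:
        raise ValidationError("need at least 5 patients")
    rows = []
    for rec, mask in zip(cohort.records, cohort.masks):
        vol, prop = overlap_metrics(mask, target, cohort.space)
        rows.append({"patient_id": rec.patient_id, "volume": vol, "proportion": prop})
    df = pd.DataFrame(rows).sort_values(
        [metric, "patient_id"], ascending=[False, True]).reset_index(drop=True)
    k = int(round(fraction * len(df)))
    df["top"] = False
    df["bottom"] = False
    df.loc[: k - 1, "top"] = True
    if k:
        df.loc[len(df) - k:, "bottom"] = True
    return df


def parcellate(volume: np.ndarray, space: BrainSpace) -> np.ndarray:
    """Regional vector: mean of ``volume`` over each parcellation region."""
    volume = np.asarray(volume, dtype=float)
    if volume.shape != space.dims:
        raise ValidationError("volume shape mismatch")
    r = space.n_regions
    out = np.empty(r)
    labels = space.parcellation
    for reg in range(1, r + 1):
        sel = labels == reg
        n = int(sel.sum())
        if n == 0:
            raise ValidationError(f"region {reg} has zero voxels")
        out[reg - 1] = volume[sel].mean()
    return out
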