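"""Readers and writers for masks, maps, tables and run configs.

Masks and voxel maps travel as NIfTI-1 (via nibabel); clinical and feature
tables as CSV; region x gene expression as TSV (first column the region
label, header row the gene ids); run configuration as a YAML key-value file.
Round-trips are bit-exact for binary masks and for float maps stored at
float64.
"""

from __future__ import annotations

import logging
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .space import BrainSpace, ClinicalRecord, LesionCohort, ValidationError

logger = logging.getLogger("gliomap")

CLINICAL_COLUMNS = [
    "patient_id", "age", "sex", "kps", "grade",
    "survival_time", "event", "dataset_id",
]
_REQUIRED = ["age", "sex", "kps", "survival_time", "event"]


def save_volume(path: str | Path, data: np.ndarray, space: BrainSpace) -> None:
    """Write a 3-D array on ``space`` as NIfTI-1."""
    if data.shape != space.dims:
        raise ValidationError(f"{path}: data shape {data.shape} != space {space.dims}")
    if data.dtype == bool:
        data = data.astype(np.uint8)
    nib.save(nib.Nifti1Image(data, space.affine), str(path))


def load_volume(path: str | Path, space: BrainSpace | None = None) -> np.ndarray:
    """Read a NIfTI volume; verify its grid against ``space`` if given."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    if space is not None and data.shape != space.dims:
        raise ValidationError(
            f"{path}: volume shape {data.shape} does not match space {space.dims}"
        )
    return data


def save_space(directory: str | Path, space: BrainSpace) -> None:
    """Write a BrainSpace (masks, parcellation, centroids, geometry) to a directory."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    save_volume(directory / "brain_mask.nii.gz", space.brain_mask, space)
    save_volume(directory / "parcellation.nii.gz",
                space.parcellation.astype(np.int32), space)
    save_volume(directory / "ventricle_mask.nii.gz", space.ventricle_mask, space)
    pd.DataFrame(space.region_centroids, columns=["x_mm", "y_mm", "z_mm"]).to_csv(
        directory / "region_centroids.csv", index_label="region"
    )
    with open(directory / "geometry.yaml", "w") as fh:
        yaml.safe_dump(
            {"dims": list(space.dims), "voxel_size": list(space.voxel_size),
             "origin": list(space.origin)}, fh)


def load_space(directory: str | Path) -> BrainSpace:
    directory = Path(directory)
    with open(directory / "geometry.yaml") as fh:
        geo = yaml.safe_load(fh)
    centroids = pd.read_csv(directory / "region_centroids.csv", index_col=0)
    space = BrainSpace(
        dims=tuple(geo["dims"]),
        voxel_size=tuple(geo["voxel_size"]),
        origin=tuple(geo["origin"]),
        brain_mask=np.asarray(
            nib.load(str(directory / "brain_mask.nii.gz")).dataobj) > 0,
        parcellation=np.asarray(
            nib.load(str(directory / "parcellation.nii.gz")).dataobj).astype(int),
        region_centroids=centroids.to_numpy(float),
        ventricle_mask=np.asarray(
            nib.load(str(directory / "ventricle_mask.nii.gz")).dataobj) > 0,
    )
    return space


def write_cohort(directory: str | Path, cohort: LesionCohort) -> None:
    """Write a cohort as one NIfTI mask per patient plus a clinical CSV."""
    directory = Path(directory)
    mask_dir = directory / "masks"
    mask_dir.mkdir(parents=True, exist_ok=True)
    save_space(directory / "space", cohort.space)
    for rec, mask in zip(cohort.records, cohort.masks):
        save_volume(mask_dir / f"{rec.patient_id}.nii.gz", mask, cohort.space)
    cohort.clinical_frame().reset_index().to_csv(
        directory / "clinical.csv", index=False, columns=CLINICAL_COLUMNS
    )
    logger.info("wrote cohort of %d patients to %s", len(cohort), directory)


def read_cohort(
    mask_dir: str | Path, clinical_table: str | Path, space: BrainSpace
) -> LesionCohort:
    """Read an aligned lesion cohort.

    Every clinical row must have a mask file ``<patient_id>.nii.gz`` (or
    ``.nii``) in ``mask_dir`` on the grid of ``space``. Rows with missing
    required fields are kept but flagged in ``cohort.flagged`` — downstream
    stages consume complete-case subsets per analysis.
    """
    mask_dir = Path(mask_dir)
    table = pd.read_csv(clinical_table)
    if table["patient_id"].duplicated().any():
        dupes = table.loc[table["patient_id"].duplicated(), "patient_id"].tolist()
        raise ValidationError(f"duplicate patient_id(s) in clinical table: {dupes}")
    masks, records = [], []
    flagged: dict[str, list[str]] = {}
    for row in table.itertuples(index=False):
        pid = str(row.patient_id)
        path = mask_dir / f"{pid}.nii.gz"
        if not path.exists():
            path = mask_dir / f"{pid}.nii"
        if not path.exists():
            raise FileNotFoundError(f"no mask file for patient {pid} in {mask_dir}")
        data = load_volume(path, space)
        masks.append(data > 0)
        missing = [c for c in _REQUIRED if pd.isna(getattr(row, c))]
        if missing:
            flagged[pid] = missing
        records.append(
            ClinicalRecord(
                patient_id=pid,
                age=float(row.age) if pd.notna(row.age) else np.nan,
                sex=str(row.sex) if pd.notna(row.sex) else "unknown",
                kps=float(row.kps) if pd.notna(row.kps) else np.nan,
                grade=str(row.grade),
                survival_time=(float(row.survival_time)
                               if pd.notna(row.survival_time) else np.nan),
                event=int(row.event) if pd.notna(row.event) else 0,
                dataset_id=str(getattr(row, "dataset_id", "D1")),
            )
        )
    cohort = LesionCohort(space, masks, records, flagged=flagged)
    if flagged:
        logger.info("flagged %d patient(s) with missing clinical fields", len(flagged))
    return cohort


def read_expression(path: str | Path) -> pd.DataFrame:
    """Region x gene TSV: first column region label, header row gene ids."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_expression(path: str | Path, expression: pd.DataFrame) -> None:
    expression.to_csv(path, sep="\t", index_label="region")


def read_config(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def write_config(path: str | Path, config: dict) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config, fh)
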