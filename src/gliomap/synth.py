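"""Synthetic toy brains, lesion cohorts, expression matrices and receptor maps.

The generators produce miniature worlds with the statistical structure the
analysis pipeline assumes — a smooth spatial lesion-occurrence field, grade
labels whose location distribution can be biased toward the ventricles,
survival times whose log-hazard depends on lesion volume, periventricular
distance and age (with right-censoring), a region x gene expression matrix
with a planted subset of genes tracking the regional lesion frequency, and
receptor maps of controlled Spearman correlation.

None of the generator choices is a claim about glioma biology: they are
fixtures whose planted ground truth downstream stages must recover. Default
cohort sizes and clinical marginals mirror the study population they emulate
(396 GBM / 190 LGG, male fraction ~0.54, KPS ~ N(82, 14) clipped, GBM median
survival ~14 months); lesion volumes are log-normal on the toy-brain scale
(the toy brain is ~10x smaller than an adult brain, so volumes are scaled
proportionally, median ~2.7 cm^3).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy import ndimage

from .space import BrainSpace, ClinicalRecord, LesionCohort, ValidationError

logger = logging.getLogger("gliomap")

_STRUCT6 = ndimage.generate_binary_structure(3, 1)  # 6-connectivity


@dataclass
class OccurrenceField:
    """Relative lesion-seed propensity, normalized to sum 1 over the brain mask."""

    space: BrainSpace
    intensity: np.ndarray

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.intensity.shape != self.space.dims:
            raise ValidationError("intensity shape does not match space")
        if not np.all(np.isfinite(self.intensity)):
            raise ValidationError("non-finite intensity")
        if np.any(self.intensity < 0):
            raise ValidationError("negative intensity")
        if np.any(self.intensity[~self.space.brain_mask] != 0):
            raise ValidationError("intensity nonzero outside brain_mask")
        total = self.intensity.sum()
        if not np.isclose(total, 1.0, atol=1e-9):
            raise ValidationError(f"intensity sums to {total}, expected 1")


@dataclass
class SimulationConfig:
    """Generative parameters of a synthetic cohort.

    survival_betas are log-hazard slopes on (lesion volume [cm^3],
    mean periventricular distance [mm], age [years]), each centered at a
    toy-scale reference value; a negative distance slope makes
    periventricular lesions more lethal.
    """

    n_gbm: int = 396
    n_lgg: int = 190
    volume_lognormal: tuple[float, float] = (1.0, 0.6)  # (mu, sigma) of log cm^3
    grade_location_beta: float = 0.05  # GBM log-propensity per mm closer to ventricle
    survival_betas: dict = dc_field(default_factory=lambda: {
        "volume": 0.08, "dist_svz": -0.10, "age": 0.02})
    censor_rate: float = 0.2
    n_genes: int = 500
    n_assoc_genes: int = 20
    assoc_effect: float = 0.9
    autocorr_length: float = 10.0  # mm
    dataset2_fraction: float = 0.15
    median_survival: dict = dc_field(default_factory=lambda: {
        "GBM": 14.0, "LGG": 40.0})  # months
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_gbm <= 0 or self.n_lgg <= 0:
            raise ValidationError("cohort counts must be positive")
        if not (0 <= self.censor_rate < 1):
            raise ValidationError("censor_rate must be in [0, 1)")
        if not (-1 < self.assoc_effect < 1):
            raise ValidationError("assoc_effect must be in (-1, 1)")
        if self.n_assoc_genes > self.n_genes:
            raise ValidationError("n_assoc_genes exceeds n_genes")


# ---------------------------------------------------------------------------
# toy reference space
# ---------------------------------------------------------------------------

def _ellipsoid(dims, center, semi) -> np.ndarray:
    grid = np.stack(
        np.meshgrid(*(np.arange(d) for d in dims), indexing="ij"), axis=-1
    ).astype(float)
    d2 = (((grid - center) / semi) ** 2).sum(axis=-1)
    return d2 <= 1.0


def make_brain_space(
    dims=(40, 48, 40),
    voxel_size=(2.0, 2.0, 2.0),
    n_regions: int = 60,
    seed: int = 0,
) -> BrainSpace:
    """Build a toy reference space: ellipsoidal brain, Voronoi parcellation,
    two ellipsoidal lateral ventricles.

    Regions are grown by nearest-seed (Voronoi) assignment in world mm from
    ``n_regions`` seed voxels sampled inside the brain mask; Voronoi cells of
    a convex mask are connected, and any stray voxels produced by
    discretization are reassigned to an adjacent region.
    """
    dims = tuple(int(d) for d in dims)
    if any(d < 16 for d in dims):
        raise ValidationError("dims must each be >= 16")
    if n_regions < 4:
        raise ValidationError("n_regions must be >= 4")
    rng = np.random.default_rng(seed)
    center = (np.asarray(dims) - 1) / 2.0
    brain = _ellipsoid(dims, center, 0.45 * np.asarray(dims))
    n_in = int(brain.sum())
    if n_regions > n_in:
        raise ValidationError(
            f"n_regions={n_regions} exceeds the {n_in}-voxel brain mask")

    # two elongated ventricles flanking the midline
    off = np.array([0.10 * dims[0], 0.0, 0.0])
    semi_v = np.asarray(dims) * np.array([0.045, 0.16, 0.05])
    vent = _ellipsoid(dims, center + off, semi_v) | _ellipsoid(dims, center - off, semi_v)
    vent &= brain

    in_idx = np.argwhere(brain)
    seeds = in_idx[rng.choice(n_in, size=n_regions, replace=False)]
    vs = np.asarray(voxel_size)
    # nearest-seed assignment in mm
    d2 = ((in_idx[:, None, :] * vs - seeds[None, :, :] * vs) ** 2).sum(axis=-1)
    labels = np.zeros(dims, dtype=np.int32)
    labels[tuple(in_idx.T)] = d2.argmin(axis=1) + 1

    labels = _repair_contiguity(labels, seeds, brain)

    centroids = np.zeros((n_regions, 3))
    origin = (0.0, 0.0, 0.0)
    for r in range(1, n_regions + 1):
        vox = np.argwhere(labels == r)
        centroids[r - 1] = np.asarray(origin) + vox.mean(axis=0) * vs
    return BrainSpace(
        dims=dims, voxel_size=tuple(voxel_size), origin=origin,
        brain_mask=brain, parcellation=labels,
        region_centroids=centroids, ventricle_mask=vent,
    )


def _repair_contiguity(labels: np.ndarray, seeds: np.ndarray, brain: np.ndarray,
                       max_iter: int = 20) -> np.ndarray:
    """Reassign voxels of non-seed connected components to adjacent regions."""
    labels = labels.copy()
    n_regions = int(labels.max())
    for _ in range(max_iter):
        stray_total = 0
        for r in range(1, n_regions + 1):
            comp, n_comp = ndimage.label(labels == r, structure=_STRUCT6)
            if n_comp <= 1:
                continue
            keep = comp[tuple(seeds[r - 1])]
            if keep == 0:  # seed voxel itself was stolen; keep largest
                sizes = ndimage.sum_labels(np.ones_like(comp), comp,
                                           np.arange(1, n_comp + 1))
                keep = int(np.argmax(sizes)) + 1
            stray = (comp > 0) & (comp != keep)
            stray_total += int(stray.sum())
            labels[stray] = 0
        if stray_total == 0:
            return labels
        # grow adjacent labels into the zeroed voxels
        holes = (labels == 0) & brain
        while holes.any():
            grown = ndimage.grey_dilation(labels, footprint=_STRUCT6)
            fill = holes & (grown > 0)
            if not fill.any():
                break
            labels[fill] = grown[fill]
            holes = (labels == 0) & brain
    return labels


# ---------------------------------------------------------------------------
# occurrence fields and lesions
# ---------------------------------------------------------------------------

def make_occurrence_field(
    space: BrainSpace, n_foci: int = 4, autocorr_length: float = 12.0,
    seed: int = 0,
) -> OccurrenceField:
    """Smooth multi-focal occurrence field: a sum of Gaussian kernels
    (mm length-scale ``autocorr_length``) at foci sampled uniformly inside
    the brain mask, masked and normalized to sum 1."""
    if n_foci < 1:
        raise ValidationError("n_foci must be >= 1")
    if autocorr_length <= 0:
        raise ValidationError("autocorr_length must be positive")
    rng = np.random.default_rng(seed)
    coords = space.world_coordinates()
    in_idx = np.argwhere(space.brain_mask)
    foci = in_idx[rng.choice(len(in_idx), size=n_foci, replace=True)]
    intensity = np.zeros(space.dims)
    for f in foci:
        fw = np.asarray(space.origin) + f * np.asarray(space.voxel_size)
        d2 = ((coords - fw) ** 2).sum(axis=-1)
        intensity += np.exp(-d2 / (2.0 * autocorr_length**2))
    intensity[~space.brain_mask] = 0.0
    intensity /= intensity.sum()
    return OccurrenceField(space, intensity)


def field_from_blob(space: BrainSpace, blob: np.ndarray,
                    inside_weight: float = 20.0) -> OccurrenceField:
    """Occurrence field concentrated on a given mask (planted-truth worlds)."""
    intensity = np.where(blob & space.brain_mask, inside_weight, 1.0)
    intensity[~space.brain_mask] = 0.0
    intensity = intensity / intensity.sum()
    return OccurrenceField(space, intensity)


def sample_lesion(
    space: BrainSpace, field: OccurrenceField, target_volume_cm3: float,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Grow one connected lesion mask.

    The seed voxel is drawn proportionally to the occurrence field; the mask
    then grows by stochastic dilation (each 6-connected boundary voxel is
    accepted with probability proportional to the field, restricted to the
    brain mask) until the target voxel count is reached exactly.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_target = max(1, int(round(target_volume_cm3 / space.voxel_volume_cm3)))
    n_brain = int(space.brain_mask.sum())
    if n_target > n_brain:
        raise ValidationError(
            f"target volume {target_volume_cm3} cm^3 exceeds brain volume")
    in_idx = np.argwhere(space.brain_mask)
    p = field.intensity[space.brain_mask]
    p = p / p.sum()
    start = in_idx[rng.choice(len(in_idx), p=p)]
    mask = np.zeros(space.dims, dtype=bool)
    mask[tuple(start)] = True
    count = 1
    while count < n_target:
        shell = ndimage.binary_dilation(mask, structure=_STRUCT6)
        shell &= space.brain_mask & ~mask
        shell_idx = np.argwhere(shell)
        if len(shell_idx) == 0:
            break  # brain mask exhausted around the lesion
        w = field.intensity[tuple(shell_idx.T)]
        wmax = w.max()
        prob = w / wmax if wmax > 0 else np.full(len(w), 0.5)
        accept = rng.random(len(shell_idx)) < prob
        if not accept.any():
            accept[int(np.argmax(w))] = True
        chosen = shell_idx[accept]
        need = n_target - count
        if len(chosen) > need:
            chosen = chosen[rng.choice(len(chosen), size=need, replace=False)]
        mask[tuple(chosen.T)] = True
        count += len(chosen)
    return mask


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

def sample_cohort(
    space: BrainSpace,
    field_gbm: OccurrenceField,
    field_lgg: OccurrenceField,
    config: SimulationConfig,
) -> LesionCohort:
    """Sample a full synthetic cohort.

    Grades are assigned by the configured counts (LGG split ~60/40 into
    astrocytoma/oligodendroglioma); GBM seed propensity is additionally
    biased toward the ventricles by ``grade_location_beta`` (log-propensity
    per mm closer to the ventricle mask); survival times are exponential with
    log-hazard linear in (volume, mean periventricular distance, age) around
    toy-scale reference values; censoring is independent uniform at the
    configured rate.
    """
    if field_gbm.space is not space or field_lgg.space is not space:
        if field_gbm.intensity.shape != space.dims or \
           field_lgg.intensity.shape != space.dims:
            raise ValidationError("fields must live on the cohort space")
    rng = np.random.default_rng(config.seed)
    svz_dist = ndimage.distance_transform_edt(
        ~space.ventricle_mask, sampling=space.voxel_size)

    if config.grade_location_beta != 0.0:
        bias = np.exp(-config.grade_location_beta * svz_dist)
        biased = field_gbm.intensity * bias
        biased[~space.brain_mask] = 0.0
        field_gbm = OccurrenceField(space, biased / biased.sum())

    n_astro = int(round(config.n_lgg * 115 / 190))
    grades = (["GBM"] * config.n_gbm + ["astrocytoma"] * n_astro
              + ["oligodendroglioma"] * (config.n_lgg - n_astro))
    mu, sigma = config.volume_lognormal
    betas = config.survival_betas
    refs = {"volume": float(np.exp(mu)), "dist_svz": 10.0, "age": 55.0}

    masks, records = [], []
    for i, grade in enumerate(grades):
        is_gbm = grade == "GBM"
        fld = field_gbm if is_gbm else field_lgg
        vol = float(rng.lognormal(mu, sigma))
        vol = min(vol, 0.25 * space.volume_cm3(space.brain_mask))
        mask = sample_lesion(space, fld, vol, seed=rng)
        vol_real = space.volume_cm3(mask)
        dist = float(svz_dist[mask].mean())
        age = float(np.clip(rng.normal(60 if is_gbm else 43, 13 if is_gbm else 14),
                            18, 90))
        sex = "male" if rng.random() < 0.54 else "female"
        kps = float(np.clip(np.round(rng.normal(82, 14)), 40, 100))
        median = config.median_survival["GBM" if is_gbm else "LGG"]
        log_hr = (betas.get("volume", 0.0) * (vol_real - refs["volume"])
                  + betas.get("dist_svz", 0.0) * (dist - refs["dist_svz"])
                  + betas.get("age", 0.0) * (age - refs["age"]))
        rate = np.log(2.0) / median * np.exp(log_hr)
        t = float(rng.exponential(1.0 / rate))
        if rng.random() < config.censor_rate:
            time, event = t * float(rng.random()), 0
        else:
            time, event = t, 1
        dataset = "D2" if rng.random() < config.dataset2_fraction else "D1"
        records.append(ClinicalRecord(
            patient_id=f"P{i:04d}", age=age, sex=sex, kps=kps, grade=grade,
            survival_time=time, event=event, dataset_id=dataset))
        masks.append(mask)
    logger.info(
        "sampled cohort: %d GBM + %d LGG, censor_rate=%.2f, seed=%d",
        config.n_gbm, config.n_lgg, config.censor_rate, config.seed)
    return LesionCohort(space, masks, records)


# ---------------------------------------------------------------------------
# expression and receptor maps
# ---------------------------------------------------------------------------

def make_expression(
    space: BrainSpace,
    regional_frequency: np.ndarray,
    n_genes: int = 500,
    n_assoc: int = 20,
    effect: float = 0.9,
    autocorr_length: float = 15.0,
    seed: int = 0,
):
    """Region x gene expression with a planted frequency-associated subset.

    Planted genes are ``effect * z(frequency) + sqrt(1-effect^2) * noise``;
    the remaining genes are spatially smooth noise (region-level Gaussian
    noise smoothed over the region-centroid distance matrix at the given mm
    length scale). All columns are z-scored (ddof=1).

    Returns
    -------
    (expression, planted)
        ``expression`` is a DataFrame (regions x genes, gene ids G0000..),
        ``planted`` the list of planted gene ids.
    """
    import pandas as pd

    f = np.asarray(regional_frequency, dtype=float)
    r = f.size
    if r < 4:
        raise ValidationError("need at least 4 regions")
    if n_assoc > n_genes:
        raise ValidationError("n_assoc exceeds n_genes")
    rng = np.random.default_rng(seed)
    if n_assoc > 0 and effect != 0.0 and np.ptp(f) == 0:
        raise ValidationError("cannot plant association on a constant frequency")
    sd = f.std(ddof=1)
    zf = (f - f.mean()) / sd if sd > 0 else np.zeros(r)

    x = np.empty((r, n_genes))
    n_noise = n_genes - n_assoc
    noise = rng.normal(size=(r, n_noise))
    if n_noise:
        d = np.linalg.norm(
            space.region_centroids[:, None, :] - space.region_centroids[None, :, :],
            axis=-1)
        w = np.exp(-(d**2) / (2.0 * autocorr_length**2))
        w /= w.sum(axis=1, keepdims=True)
        noise = w @ noise
    cols = np.arange(n_genes)
    assoc_cols = np.sort(rng.choice(n_genes, size=n_assoc, replace=False))
    noise_cols = np.setdiff1d(cols, assoc_cols)
    x[:, noise_cols] = noise
    x[:, assoc_cols] = (effect * zf[:, None]
                        + np.sqrt(1 - effect**2) * rng.normal(size=(r, n_assoc)))
    x = (x - x.mean(axis=0)) / x.std(axis=0, ddof=1)
    genes = [f"G{j:04d}" for j in range(n_genes)]
    planted = [genes[j] for j in assoc_cols]
    return pd.DataFrame(x, index=np.arange(1, r + 1), columns=genes), planted


def make_receptor_map(
    regional_frequency: np.ndarray, rho_target: float, seed: int = 0
) -> np.ndarray:
    """Regional receptor density with a controlled Spearman correlation.

    Gaussian-copula construction: the frequency ranks are mapped to normal
    scores, mixed with independent noise at the Pearson level
    ``2*sin(pi*rho_target/6)`` (the bivariate-normal inverse of the
    Spearman correlation), achieving Spearman rho within ~0.1 of the target
    for R >= 100.
    """
    from scipy.stats import norm, rankdata

    f = np.asarray(regional_frequency, dtype=float)
    if np.ptp(f) == 0:
        raise ValidationError("correlation with a constant vector is undefined")
    if not (-1 < rho_target < 1):
        raise ValidationError("rho_target must be in (-1, 1)")
    rng = np.random.default_rng(seed)
    r_pearson = 2.0 * np.sin(np.pi * rho_target / 6.0)
    z1 = norm.ppf((rankdata(f) - 0.5) / f.size)
    z2 = r_pearson * z1 + np.sqrt(1 - r_pearson**2) * rng.normal(size=f.size)
    return z2
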