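"""Voxel-based lesion-symptom mapping with permutation thresholds.

At each sufficiently covered voxel, the outcome (grade indicator or overall
survival) is regressed on [lesion indicator, covariates, intercept] by
ordinary least squares; the map statistic is the t value of the lesion
coefficient (for a binary outcome this is a linear probability model).
Significance is assessed by Freedman-Lane residual permutation: the
covariate-only model's residuals are permuted, refitted voxelwise, and the
threshold is either the (1-alpha) quantile of the per-permutation maximum
statistic over tested voxels (familywise "maxstat" mode, the default) or the
per-voxel (1-alpha) quantile of each voxel's own null ("voxelwise" mode).

Implementation note: with the covariates projected out (Frisch-Waugh), the
full-model t of the lesion coefficient is a deterministic function of the
partial correlation between the residualized lesion indicator and the
residualized outcome, which lets all voxels and all permutations be computed
with dense matrix products.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator

from .space import LesionCohort, ValidationError

logger = logging.getLogger("gliomap")

_EPS_RANK = 1e-10


@dataclass
class VLSMResult:
    """Fitted voxelwise map with its permutation null."""

    t_map: np.ndarray
    coverage_map: np.ndarray
    tested_mask: np.ndarray
    null_maxima: np.ndarray
    threshold: float
    significant_mask: np.ndarray
    config: dict = field(default_factory=dict)


def _residualizer(z: np.ndarray):
    """Return a function projecting out the column space of z (with intercept)."""
    q, _ = np.linalg.qr(z)

    def project(a: np.ndarray) -> np.ndarray:
        return a - q @ (q.T @ a)

    return project, z.shape[1]


def _t_from_partial(lt: np.ndarray, yt: np.ndarray, lnorm2: np.ndarray,
                    df: int, y_scale: float) -> np.ndarray:
    """t of the lesion coefficient from residualized lesion columns and outcome."""
    ynorm2 = float(yt @ yt)
    if ynorm2 <= 1e-18 * max(y_scale, 1e-300):
        return np.zeros(lt.shape[1])  # outcome in the covariate span
    denom = np.sqrt(lnorm2 * ynorm2)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (lt.T @ yt) / denom
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = r * np.sqrt(df / np.maximum(1.0 - r**2, 1e-300))
    return t


class VoxelLesionSymptomMapper(BaseEstimator):
    """Covariate-adjusted voxelwise lesion-outcome association.

    Parameters
    ----------
    min_coverage : int
        A voxel is tested only if lesioned in at least ``min_coverage``
        patients and intact in at least ``min_coverage``.
    n_perm : int
        Number of Freedman-Lane permutations (>= 20).
    alpha : float
        Familywise (maxstat) or per-voxel (voxelwise) level.
    mode : {"maxstat", "voxelwise"}
    tail : {"two", "greater", "less"}
        Direction of the alternative on the lesion t value.
    freedman_lane : bool
        If False, permute the raw outcome instead of reduced-model residuals.
    seed : int

    Attributes (after :meth:`fit`)
    ------------------------------
    t_map_, coverage_map_, tested_mask_, null_maxima_, threshold_,
    significant_mask_, result_
    """

    def __init__(self, min_coverage: int = 5, n_perm: int = 500,
                 alpha: float = 0.05, mode: str = "maxstat",
                 tail: str = "two", freedman_lane: bool = True, seed: int = 0):
        self.min_coverage = min_coverage
        self.n_perm = n_perm
        self.alpha = alpha
        self.mode = mode
        self.tail = tail
        self.freedman_lane = freedman_lane
        self.seed = seed

    # -- internals ----------------------------------------------------------
    def _directional(self, t: np.ndarray) -> np.ndarray:
        if self.tail == "two":
            return np.abs(t)
        if self.tail == "greater":
            return t
        if self.tail == "less":
            return -t
        raise ValidationError(f"unknown tail {self.tail!r}")

    def fit(self, cohort: LesionCohort, outcome: np.ndarray,
            covariates: np.ndarray | None = None) -> "VoxelLesionSymptomMapper":
        """Fit the voxelwise map and its permutation threshold."""
        if self.min_coverage < 2:
            raise ValidationError("min_coverage must be >= 2")
        if self.n_perm < 20:
            raise ValidationError("n_perm < 20: permutation quantile unstable")
        if self.mode not in ("maxstat", "voxelwise"):
            raise ValidationError(f"unknown mode {self.mode!r}")
        y = np.asarray(outcome, dtype=float)
        n = len(cohort)
        if y.shape != (n,):
            raise ValidationError("outcome length does not match cohort")
        if covariates is None:
            z = np.ones((n, 1))
        else:
            covariates = np.atleast_2d(np.asarray(covariates, dtype=float))
            if covariates.shape[0] != n:
                covariates = covariates.T
            z = np.column_stack([covariates, np.ones(n)])
        if not np.all(np.isfinite(y)) or not np.all(np.isfinite(z)):
            raise ValidationError("non-finite outcome or covariates")

        lesions = cohort.mask_stack()  # n x V
        coverage = lesions.sum(axis=0)
        candidate = (coverage >= self.min_coverage) & (coverage <= n - self.min_coverage)
        project, p_cov = _residualizer(z)
        df = n - p_cov - 1  # covariates (incl. intercept) + lesion column
        if df < 1:
            raise ValidationError("not enough patients for the design")

        lt = project(lesions[:, candidate].astype(float))
        lnorm2 = (lt**2).sum(axis=0)
        ok = lnorm2 > _EPS_RANK * n
        n_rankdef = int((~ok).sum())
        if n_rankdef:
            logger.info("excluded %d rank-deficient voxel(s)", n_rankdef)
        tested_flat = np.zeros(lesions.shape[1], dtype=bool)
        tested_flat[np.flatnonzero(candidate)[ok]] = True
        lt, lnorm2 = lt[:, ok], lnorm2[ok]

        y_scale = float(y @ y)
        yt = project(y)
        t_tested = _t_from_partial(lt, yt, lnorm2, df, y_scale)

        rng = np.random.default_rng(self.seed)
        base = yt if self.freedman_lane else y
        perms = np.stack([rng.permutation(base) for _ in range(self.n_perm)], axis=1)
        et = project(perms)  # residualize permuted outcomes
        enorm2 = (et**2).sum(axis=0)
        degenerate = enorm2 <= 1e-18 * max(y_scale, 1e-300)
        denom = np.sqrt(np.outer(lnorm2, enorm2))
        with np.errstate(invalid="ignore", divide="ignore"):
            r_null = (lt.T @ et) / denom
        r_null = np.clip(r_null, -1.0, 1.0)
        t_null = r_null * np.sqrt(df / np.maximum(1.0 - r_null**2, 1e-300))
        t_null[:, degenerate] = 0.0

        stat = self._directional(t_tested)
        stat_null = self._directional(t_null)
        if self.mode == "maxstat":
            null_maxima = stat_null.max(axis=0) if stat_null.size else np.zeros(self.n_perm)
            threshold = float(np.quantile(null_maxima, 1.0 - self.alpha))
            sig_flat = stat > threshold
        else:
            per_voxel_thr = np.quantile(stat_null, 1.0 - self.alpha, axis=1)
            sig_flat = stat > per_voxel_thr
            null_maxima = stat_null.max(axis=0) if stat_null.size else np.zeros(self.n_perm)
            threshold = float(np.nan)

        dims = cohort.space.dims
        t_map = np.zeros(dims)
        t_map.reshape(-1)[tested_flat] = t_tested
        significant = np.zeros(dims, dtype=bool)
        significant.reshape(-1)[tested_flat] = sig_flat

        self.t_map_ = t_map
        self.coverage_map_ = coverage.reshape(dims).astype(np.int32)
        self.tested_mask_ = tested_flat.reshape(dims)
        self.null_maxima_ = null_maxima
        self.threshold_ = threshold
        self.significant_mask_ = significant
        self.result_ = VLSMResult(
            t_map=t_map, coverage_map=self.coverage_map_,
            tested_mask=self.tested_mask_, null_maxima=null_maxima,
            threshold=threshold, significant_mask=significant,
            config={"n_perm": self.n_perm, "alpha": self.alpha, "mode": self.mode,
                    "tail": self.tail, "min_coverage": self.min_coverage,
                    "freedman_lane": self.freedman_lane, "seed": self.seed},
        )
        logger.info(
            "VLSM: %d tested voxels, mode=%s tail=%s, %d significant",
            int(tested_flat.sum()), self.mode, self.tail, int(significant.sum()))
        return self


# -- thin functional wrappers ------------------------------------------------

def voxelwise_stat(cohort: LesionCohort, outcome, covariates=None,
                   min_coverage: int = 5):
    """(t_map, coverage_map, tested_mask) without permutation inference."""
    m = VoxelLesionSymptomMapper(min_coverage=min_coverage, n_perm=20, seed=0)
    m.fit(cohort, outcome, covariates)
    return m.t_map_, m.coverage_map_, m.tested_mask_


def permutation_threshold(cohort: LesionCohort, outcome, covariates=None,
                          n_perm: int = 500, alpha: float = 0.05,
                          mode: str = "maxstat", tail: str = "two",
                          min_coverage: int = 5, seed: int = 0) -> VLSMResult:
    m = VoxelLesionSymptomMapper(min_coverage=min_coverage, n_perm=n_perm,
                                 alpha=alpha, mode=mode, tail=tail, seed=seed)
    m.fit(cohort, outcome, covariates)
    return m.result_


def _design(cohort: LesionCohort) -> tuple[np.ndarray, np.ndarray]:
    """Default covariates (age, sex, tumor volume) and complete-case filter."""
    df = cohort.clinical_frame()
    vol = np.array([cohort.space.volume_cm3(m) for m in cohort.masks])
    sex = (df["sex"] == "male").to_numpy(float)
    cov = np.column_stack([df["age"].to_numpy(float), sex, vol])
    complete = np.all(np.isfinite(cov), axis=1)
    return cov, complete


def derive_rois(cohort: LesionCohort, n_perm: int = 500, alpha: float = 0.05,
                mode: str = "maxstat", min_coverage: int = 5, seed: int = 0
                ) -> tuple[np.ndarray, np.ndarray]:
    """(ROI1, ROI2): grade-associated and short-survival-associated masks.

    ROI1: voxels whose lesioning predicts the GBM label (positive tail),
    adjusting for age, sex and tumor volume. ROI2: among GBM patients with
    observed survival, voxels predicting shorter overall survival (negative
    tail). Either may come back empty; downstream stages must handle that.
    """
    cov, complete = _design(cohort)
    grade = np.array([r.is_gbm for r in cohort.records], dtype=float)
    sub = cohort.subset(complete) if not complete.all() else cohort
    if not complete.all():
        logger.info("ROI1: excluded %d incomplete-covariate patients",
                    int((~complete).sum()))
        cov_sub = cov[complete]
        grade_sub = grade[complete]
    else:
        cov_sub, grade_sub = cov, grade
    roi1 = VoxelLesionSymptomMapper(
        min_coverage=min_coverage, n_perm=n_perm, alpha=alpha, mode=mode,
        tail="greater", seed=seed).fit(sub, grade_sub, cov_sub).significant_mask_
    if not roi1.any():
        logger.warning("ROI1 is empty at alpha=%s", alpha)

    df = cohort.clinical_frame()
    is_gbm = np.array([r.is_gbm for r in cohort.records])
    has_os = np.isfinite(df["survival_time"].to_numpy(float))
    keep = is_gbm & has_os & complete
    gbm = cohort.subset(keep)
    os_months = df["survival_time"].to_numpy(float)[keep]
    roi2 = VoxelLesionSymptomMapper(
        min_coverage=min_coverage, n_perm=n_perm, alpha=alpha, mode=mode,
        tail="less", seed=seed + 1).fit(
            gbm, os_months, cov[keep]).significant_mask_
    if not roi2.any():
        logger.warning("ROI2 is empty at alpha=%s", alpha)
    return roi1, roi2
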