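"""Tumor location features and survival statistics.

Location features per patient: tumor volume; overlap volume/proportion with
the predilection mask and with the VLSM-derived ROI1/ROI2; mean Euclidean
distance (mm, anisotropic voxels respected) to small spheres at the ROI mass
centers and to the ventricle mask (the periventricular / SVZ distance).

Survival statistics: Kaplan-Meier curves, two-group log-rank tests, quartile
grouping of any feature, the fixed six-gene prognostic risk score with its
median split, and the IPCW (inverse-probability-of-censoring-weighted)
cumulative/dynamic time-dependent AUC.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from scipy import ndimage

from .frequency import overlap_metrics
from .space import BrainSpace, LesionCohort, ValidationError

logger = logging.getLogger("gliomap")


# ---------------------------------------------------------------------------
# distance maps and location features
# ---------------------------------------------------------------------------

def distance_map(space: BrainSpace, target_mask: np.ndarray) -> np.ndarray:
    """Per-voxel Euclidean distance (mm) to the nearest target voxel."""
    target = np.asarray(target_mask, dtype=bool)
    if target.shape != space.dims:
        raise ValidationError("target mask not on the space grid")
    if not target.any():
        raise ValidationError("empty target mask")
    return ndimage.distance_transform_edt(~target, sampling=space.voxel_size)


def roi_center_mask(roi_mask: np.ndarray, space: BrainSpace,
                    radius_mm: float = 4.0) -> np.ndarray:
    """Sphere of ``radius_mm`` at the ROI's voxel-rounded center of mass,
    clipped to the brain mask (default radius: 2 voxels at 2 mm)."""
    roi = np.asarray(roi_mask, dtype=bool)
    if not roi.any():
        raise ValidationError("empty ROI")
    com = np.argwhere(roi).mean(axis=0)
    center = np.round(com).astype(int)
    center = np.clip(center, 0, np.asarray(space.dims) - 1)
    if not space.brain_mask[tuple(center)]:
        dist, idx = ndimage.distance_transform_edt(
            ~space.brain_mask, sampling=space.voxel_size, return_indices=True)
        center = idx[:, center[0], center[1], center[2]]
        logger.warning("ROI mass center outside brain mask; snapped to nearest")
    coords = space.world_coordinates()
    cw = np.asarray(space.origin) + center * np.asarray(space.voxel_size)
    sphere = ((coords - cw) ** 2).sum(axis=-1) <= radius_mm**2
    out = sphere & space.brain_mask
    if not out.any():  # radius below voxel size
        out = np.zeros(space.dims, dtype=bool)
        out[tuple(center)] = True
    return out


def mean_tumor_distance(lesion: np.ndarray, dist_map: np.ndarray) -> float:
    """Mean of a distance map over the lesion voxels (mm)."""
    lesion = np.asarray(lesion, dtype=bool)
    if not lesion.any():
        raise ValidationError("empty lesion")
    return float(dist_map[lesion].mean())


FEATURE_COLUMNS = [
    "tumor_volume_cm3",
    "overlap_volume_pred_cm3", "overlap_prop_pred",
    "overlap_volume_roi1_cm3", "overlap_prop_roi1",
    "overlap_volume_roi2_cm3", "overlap_prop_roi2",
    "dist_roi1_mm", "dist_roi2_mm", "dist_svz_mm",
]


def build_feature_table(cohort: LesionCohort, predilection: np.ndarray,
                        roi1: np.ndarray, roi2: np.ndarray,
                        svz_mask: np.ndarray | None = None,
                        radius_mm: float = 4.0) -> pd.DataFrame:
    """Per-patient location features (one row per patient, indexed by id).

    Empty ROI masks yield NaN sentinel columns, recorded in
    ``table.attrs['empty_rois']`` and logged — never silently dropped.
    """
    space = cohort.space
    if svz_mask is None:
        svz_mask = space.ventricle_mask
    empty = []
    dmaps, centers = {}, {}
    for name, roi in (("roi1", roi1), ("roi2", roi2)):
        roi = np.asarray(roi, dtype=bool)
        if roi.any():
            centers[name] = roi_center_mask(roi, space, radius_mm)
            dmaps[name] = distance_map(space, centers[name])
        else:
            empty.append(name)
            logger.warning("%s is empty: its feature columns are NaN", name)
    dm_svz = distance_map(space, svz_mask)

    rows = []
    for rec, mask in zip(cohort.records, cohort.masks):
        row = {"patient_id": rec.patient_id,
               "tumor_volume_cm3": space.volume_cm3(mask)}
        for name, target in (("pred", predilection), ("roi1", roi1), ("roi2", roi2)):
            target = np.asarray(target, dtype=bool)
            if target.any():
                vol, prop = overlap_metrics(mask, target, space)
            else:
                vol, prop = np.nan, np.nan
            row[f"overlap_volume_{name}_cm3"] = vol
            row[f"overlap_prop_{name}"] = prop
        for name in ("roi1", "roi2"):
            row[f"dist_{name}_mm"] = (mean_tumor_distance(mask, dmaps[name])
                                      if name in dmaps else np.nan)
        row["dist_svz_mm"] = mean_tumor_distance(mask, dm_svz)
        rows.append(row)
    table = pd.DataFrame(rows).set_index("patient_id")
    table.attrs["empty_rois"] = empty
    return table


# ---------------------------------------------------------------------------
# survival statistics
# ---------------------------------------------------------------------------

def km_curve(times, events) -> tuple[np.ndarray, np.ndarray]:
    """Product-limit survival curve; returns (times, S(t)) starting at (0, 1)."""
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    if t.size == 0:
        raise ValidationError("empty input")
    if np.any(t < 0):
        raise ValidationError("negative times")
    kmf = KaplanMeierFitter()
    kmf.fit(t, e)
    sf = kmf.survival_function_
    return sf.index.to_numpy(float), sf.iloc[:, 0].to_numpy(float)


def logrank_test(group_a: tuple, group_b: tuple) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi-square statistic, p), 1 df."""
    ta, ea = (np.asarray(v, dtype=float) for v in group_a)
    tb, eb = (np.asarray(v, dtype=float) for v in group_b)
    if ta.size == 0 or tb.size == 0:
        raise ValidationError("both groups must be nonempty")
    if int(ea.sum()) == 0 and int(eb.sum()) == 0:
        raise ValidationError("no events in either group")
    res = _ll_logrank(ta, tb, event_observed_A=ea.astype(int),
                      event_observed_B=eb.astype(int))
    return float(res.test_statistic), float(res.p_value)


def quartile_groups(feature: pd.Series) -> tuple[list, list]:
    """(top-quartile ids, bottom-quartile ids) using linear-interpolation
    (type-7) quantiles; boundary ties included on both sides."""
    s = feature.dropna()
    if len(s) < 8:
        raise ValidationError("need at least 8 patients")
    vals = s.to_numpy(float)
    if np.ptp(vals) == 0:
        raise ValidationError("constant feature has no quartiles")
    q1, q3 = np.quantile(vals, [0.25, 0.75])
    top = list(s.index[vals >= q3])
    bottom = list(s.index[vals <= q1])
    if len(top) + len(bottom) > int(np.ceil(len(s) / 2)) + 1:
        logger.info("quartile ties: %d top + %d bottom of %d",
                    len(top), len(bottom), len(s))
    return top, bottom


# ---------------------------------------------------------------------------
# six-gene risk score
# ---------------------------------------------------------------------------

#: Cox-model coefficients of the published six-gene prognostic signature.
DEFAULT_RISK_COEFFICIENTS = {
    "SNCB": 0.1507, "GRIN1": -0.2949, "HPCA": 0.0044,
    "CPNE6": 0.1415, "GABRD": 0.2997, "ATP2B3": -0.081,
}


@dataclass
class RiskModel:
    """Linear gene-expression risk score. The score is scale-agnostic: it is
    applied to expression on whatever scale the coefficients were fit on."""

    coefficients: dict = field(
        default_factory=lambda: dict(DEFAULT_RISK_COEFFICIENTS))

    def __post_init__(self) -> None:
        if not self.coefficients:
            raise ValidationError("risk model has no coefficients")


def risk_score(expression: pd.DataFrame, model: RiskModel | None = None
               ) -> pd.Series:
    """Per-patient risk score = sum(coefficient x gene expression).

    ``expression`` is patients x genes; every model gene must be present.
    """
    model = model or RiskModel()
    missing = [g for g in model.coefficients if g not in expression.columns]
    if missing:
        raise ValidationError(f"expression lacks model gene(s): {missing}")
    score = sum(coef * expression[g].astype(float)
                for g, coef in model.coefficients.items())
    score.name = "risk_score"
    return score


def median_split(scores: pd.Series) -> tuple[list, list]:
    """(high ids, low ids): strictly above the median vs at-or-below."""
    med = float(scores.median())
    high = list(scores.index[scores > med])
    low = list(scores.index[scores <= med])
    return high, low


# ---------------------------------------------------------------------------
# time-dependent ROC
# ---------------------------------------------------------------------------

def _censoring_survival(times: np.ndarray, events: np.ndarray):
    """Kaplan-Meier estimate of the censoring distribution G(t)."""
    kmf = KaplanMeierFitter()
    kmf.fit(times, 1 - events)
    grid = kmf.survival_function_.index.to_numpy(float)
    surv = kmf.survival_function_.iloc[:, 0].to_numpy(float)

    def g(t: np.ndarray, left: bool = False) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        if left:
            t = np.nextafter(t, -np.inf)
        idx = np.searchsorted(grid, t, side="right") - 1
        out = np.where(idx >= 0, surv[np.clip(idx, 0, None)], 1.0)
        return out

    return g


def time_dependent_auc(scores, times, events, horizon_months: float) -> float:
    """Cumulative-case / dynamic-control AUC at a horizon with IPCW.

    Cases are patients with an observed event by the horizon (weight
    1/G(T-)); controls are patients still at risk past the horizon (weight
    1/G(horizon)), with G the Kaplan-Meier censoring-survival estimate.
    Without censoring this reduces to the plain rank-sum AUC of the
    indicator of death by the horizon.
    """
    s = np.asarray(scores, dtype=float)
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    tau = float(horizon_months)
    case = (t <= tau) & (e == 1)
    control = t > tau
    if not case.any():
        raise ValidationError("no cases by the horizon")
    if not control.any():
        raise ValidationError("no controls past the horizon")
    g = _censoring_survival(t, e)
    w_case = 1.0 / g(t[case], left=True)
    w_ctrl = np.full(int(control.sum()), 1.0 / max(float(g([tau])[0]), 1e-12))
    sc, sn = s[case], s[control]
    greater = (sc[:, None] > sn[None, :]).astype(float)
    ties = (sc[:, None] == sn[None, :]).astype(float)
    ww = np.outer(w_case, w_ctrl)
    return float((ww * (greater + 0.5 * ties)).sum() / ww.sum())
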