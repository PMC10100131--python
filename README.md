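# gliomap

Where in the brain do gliomas occur, and does location matter? `gliomap` is
a Python toolkit for the analysis chain that answers this from binary
lesion masks in a common reference space: voxelwise **tumor frequency
maps**; covariate-adjusted **voxel-based lesion-symptom mapping** (VLSM)
with permutation-derived thresholds, separating glioblastoma (GBM)–
associated from lower-grade-glioma (LGG)–associated territory and deriving
short-survival regions; **imaging transcriptomics** — partial least
squares between regional frequency and a region × gene expression matrix,
with spatial-autocorrelation-preserving surrogate nulls, gene ranking and
set enrichment; **receptor-map correlation**; **tumor-location features**
(overlap with predilection/ROI masks, Euclidean distances to ROI centers
and the periventricular zone); **survival statistics** (quartile
Kaplan–Meier log-rank, a fixed six-gene risk score with median split,
IPCW time-dependent ROC); and **one-year survival classification** with
linear/radial SVMs under repeated stratified resampling.

It is written for researchers in lesion-network and tumor-location mapping
who want a tested, scriptable re-implementation of this pipeline, plus a
synthetic-cohort generator so every stage can be exercised and calibrated
without access-restricted clinical data.

## The statistics at the core

- Frequency map: `f(v) = (1/N) Σ_i 1{lesion_i covers v}`; the predilection
  mask keeps the top 10% of nonzero-frequency voxels.
- VLSM: per voxel, OLS of outcome on `[lesion, age, sex, volume, 1]`; the
  map is the lesion-coefficient t; the threshold is the 95th percentile of
  the max-|t| distribution over Freedman–Lane permutations (n = 500).
- PLS: with `y = z(√frequency)` and z-scored expression `X`, SVD of the
  cross-covariance `Xᵀy/(R−1) = USVᵀ`; `U` ranks genes, `S` is tested
  against variogram-matched spatial surrogates,
  `p = (1 + #{S_null ≥ S})/(n_null + 1)`.
- Risk score: `0.1507·SNCB − 0.2949·GRIN1 + 0.0044·HPCA + 0.1415·CPNE6 +
  0.2997·GABRD − 0.081·ATP2B3`, median split, IPCW cumulative/dynamic AUC
  at 12 and 36 months.
- SVM: per repeat, stratified 80% of each dataset pooled for training,
  grid-searched by 10-fold CV AUC, scored on the out-of-bag pool; reported
  as mean ± SD AUC over repeats with held-out permutation importance.

See `docs/methods.md` for assumptions, parameter defaults and limitations.

## Worked example

```python
import numpy as np
import gliomap as gm

# a toy world: 24^3 grid, 2 mm voxels, 30 regions, two ventricles
space = gm.make_brain_space(dims=(24, 24, 24), n_regions=30, seed=0)
field = gm.make_occurrence_field(space, n_foci=4, autocorr_length=12, seed=3)
cfg = gm.SimulationConfig(n_gbm=120, n_lgg=80, seed=9,
                          volume_lognormal=(0.3, 0.5))
cohort = gm.sample_cohort(space, field, field, cfg)

fmap = gm.build_frequency_map(cohort, "GBM")
pred = gm.top_fraction_mask(fmap, q=0.10)
print(f"peak frequency {fmap.values.max():.2f}, "
      f"predilection mask {int(pred.mask.sum())} voxels")

roi1, roi2 = gm.derive_rois(cohort, n_perm=200, seed=5)
table = gm.build_feature_table(cohort, pred.mask, roi1, roi2)
clin = cohort.clinical_frame()
top, bottom = gm.quartile_groups(table["dist_svz_mm"])
chi2, p = gm.logrank_test(
    (clin.loc[top, "survival_time"], clin.loc[top, "event"]),
    (clin.loc[bottom, "survival_time"], clin.loc[bottom, "event"]))
print(f"SVZ-distance quartile log-rank: chi2={chi2:.2f}, p={p:.1e}")
```

prints, with these seeds:

```
peak frequency 0.18, predilection mask 465 voxels
SVZ-distance quartile log-rank: chi2=17.60, p=2.7e-05
```

A peak frequency of 0.18 means the most-affected voxel is lesioned in 18%
of the 120 GBM patients; the log-rank p ≈ 3e-5 detects the generator's
default hazard coupling to periventricular distance (patients whose tumors
sit nearer the ventricles die sooner). The same stages are available from
the shell via the `gliomap` CLI (`simulate`, `freqmap`, `vlsm`, `pls`,
`receptors`, `features`, `survival`, `predict`).

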