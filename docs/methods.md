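# Methods

`gliomap` re-implements, as a tested pipeline on a common voxel grid, the
analysis chain used in spatial-epidemiology studies of glioma: tumor
frequency mapping, covariate-adjusted voxel-based lesion-symptom mapping
(VLSM) with permutation thresholds, imaging-transcriptomics association by
partial least squares with spatial-autocorrelation nulls, receptor-map
correlation, tumor-location feature extraction, survival statistics, and
SVM-based one-year survival classification. Because the clinical imaging,
transcriptomic and survival data such studies use are access-restricted, the
package ships a synthetic-world generator with the statistical structure the
pipeline assumes, and every stage is validated on planted ground truth.

## Reference space and conventions

A `BrainSpace` is a voxel grid (`dims`, `voxel_size` in mm, `origin`), a
brain mask, an integer parcellation with per-region centroids, and a
lateral-ventricle mask used as the subventricular-zone (SVZ) proxy. Voxel
indices are 0-based; world mm = origin + index × voxel size; distances are
mm and volumes cm³ (voxel count × voxel volume / 1000). Masks and maps are
NIfTI-1; tables are CSV; expression is a region × gene TSV.

Patients with missing clinical fields are flagged at load time and excluded
per analysis (complete-case), never silently dropped; every exclusion is
logged with a count, and every stochastic operation logs its seed.

## Frequency maps and predilection masks

The frequency map is the voxelwise proportion of patients whose lesion
covers the voxel (weight 1 per patient — the only reading under which the
map is a "frequency proportion" in [0, 1]). The predilection mask keeps the
top 10% (configurable) highest-frequency voxels among voxels with nonzero
frequency; a whole-brain base is available behind a flag but would make the
mask depend on brain-mask size rather than tumor data. Ties at the cutoff
are all included (deterministic and order-independent; the realized
fraction is logged when it exceeds the target). Overlap "proportion" is
denominated by the individual tumor's volume.

## VLSM

At each voxel lesioned in ≥ `min_coverage` patients (default 5) and intact
in as many, the outcome is regressed by OLS on [lesion indicator,
covariates, intercept]; the map statistic is the t of the lesion
coefficient (a linear probability model for binary outcomes — per-voxel
logistic fits are unstable at low coverage). Default covariates are age,
sex and tumor volume. Inference is by Freedman–Lane residual permutation:
the covariate-only model's residuals are permuted and refitted voxelwise.
The default threshold is the 95th percentile of the per-permutation maximum
statistic over tested voxels (familywise "maxstat" control); a per-voxel
("voxelwise") mode and a naive outcome-permutation scheme are exposed as
options, as are the permutation count (default 500) and alpha. Voxels whose
residualized lesion indicator is numerically zero (collinear with the
covariates) are excluded and logged, and an outcome lying in the covariate
span yields a zero map rather than numerical noise.

Implementation: with covariates projected out (Frisch–Waugh), the lesion t
is a function of the partial correlation between residualized lesion column
and residualized outcome, so all voxels × all permutations reduce to two
dense matrix products; 200 permutations on a 16³ grid with n = 60 take
~10 ms.

ROI1 (grade-associated) uses the GBM indicator with a positive one-sided
tail; ROI2 (short-survival-associated) uses overall survival in months
among GBM patients with a negative tail. Survival enters VLSM uncensored
(a documented limitation, matching common VLSM practice); either ROI may
come back empty and downstream stages fill the corresponding features with
flagged NaNs.

## PLS against regional expression

The regional frequency vector is square-rooted (skewness reduction) and
z-scored; expression columns are z-scored (ddof = 1 throughout). The
association is the SVD of the cross-covariance Xᵀy/(R−1): left singular
vectors are unit-norm gene loadings, singular values the captured
covariance (the 1/(R−1) convention makes them comparable across runs). With
one response the decomposition is rank one — component 1 is the normalized
Xᵀy — and extra components are only meaningful for multi-response inputs.

Significance uses variogram-matching surrogate maps on the region
centroids rather than a spherical spin (a volumetric parcellation including
subcortex has no sphere to spin on). Each surrogate permutes the map,
smooths it with a Gaussian distance kernel at the best of eight candidate
length scales, adds a white-noise nugget fitted by regressing the target
variogram on the smoothed one, and rescales to the original mean and
variance. The variogram is matched over the shortest 50% of region pairs in
8 equal-count bins: short-range autocorrelation is what drives spurious
map-to-map alignment, whereas the long-range variogram of a nonstationary
focal map (high near foci, low far away) is not reproducible by any
stationary surrogate and is left free. With this choice the component-1
spin p-value is uniform under no planted association (KS p ≈ 0.7 across
200 re-drawn worlds) with type-I error ~3% at nominal 5%; matching the full
distance range instead makes the test strongly anticonservative. Only the
tumor map is surrogate-randomized; expression is held fixed. The p-value is
(1 + #{null ≥ observed})/(n_null + 1).

Gene ranking is by signed component loading (ties by gene id; negating the
response exactly reverses the order). Set enrichment is competitive: Welch
t between member and non-member loadings, p by set-size-preserving label
resampling (two-sided), Benjamini–Hochberg across sets, significant at
q < 0.05. Sets smaller than 5 background genes, or spanning the whole
background, are skipped with a warning. Receptor maps are compared by
Spearman correlation with a two-sided p from the same surrogate family.

## Location features and survival

Distance maps are exact Euclidean distance transforms honoring anisotropic
voxel sizes. ROI "center masks" are spheres (default radius 4 mm = 2 voxels
— kept point-like but nonempty; the choice is a free parameter) at the
voxel-rounded center of mass, snapped to the nearest in-brain voxel if
needed. The periventricular (SVZ) distance map is the distance transform of
the ventricle mask; per-tumor statistics are means over tumor voxels. The
feature table carries tumor volume; overlap volume/proportion with the
predilection mask, ROI1 and ROI2; and mean distances to the ROI centers and
the SVZ.

Kaplan–Meier curves and two-group log-rank tests come from lifelines
(simultaneous risk sets; χ² with 1 df). Quartile grouping uses
linear-interpolation (type-7) quantiles with boundary ties included on both
sides (stated because tie handling changes membership). The six-gene risk
score is a fixed linear combination (SNCB +0.1507, GRIN1 −0.2949, HPCA
+0.0044, CPNE6 +0.1415, GABRD +0.2997, ATP2B3 −0.081) applied to expression
on whatever scale the coefficients were fit on — the score is
scale-agnostic and the package does not refit it. The median split sends
strictly-above to the high group. The time-dependent AUC is the
cumulative-case/dynamic-control estimator with inverse-probability-of-
censoring weights from a Kaplan–Meier estimate of the censoring
distribution (left limits at event times); without censoring it reduces
exactly to the rank-sum AUC of "dead by horizon", and it agrees with
scikit-survival's implementation to 1e-10.

## One-year survival classification

Labels: died before 12 months → 1; survived to 12 months (event or
censored later) → 0; censored before 12 months → excluded and flagged
(status unknown). Per repeat, 80% of each dataset is drawn stratified by
label and pooled for training (this pooling is what controls
cohort-composition drift between datasets); the out-of-bag patients are the
test pool. Features (ROI overlaps and distances, tumor volume, age, sex
0/1, KPS) are standardized with training statistics inside the pipeline;
hyperparameters (cost 2⁻⁵..2⁵, radial width 2⁻⁷..2³, log-2 ladders) are
chosen by 10-fold cross-validated AUC on the training pool only; the refit
model is scored by AUC on the test pool. Defaults follow the published
scheme (100 repeats); the bundled studies use 8 repeats and coarser ladders
(step 2) to keep desk-scale runtimes. Feature importance is permutation
importance on the held-out pool (mean AUC drop over 10 shuffles, averaged
over repeats) — a reproducible stand-in for "conditional" importance
scores whose exact definition varies between packages. Draws missing a
class are redrawn (≤ 10 times), and the whole result is bit-reproducible
from one integer seed via spawned child seeds.

## Synthetic worlds

The generator builds an ellipsoidal toy brain with a Voronoi parcellation
(nearest-seed in mm; convex cells stay contiguous, with a repair pass for
discretization strays) and two ellipsoidal ventricles. Lesion occurrence
follows a smooth multi-focal field (sum of Gaussian kernels at sampled
foci); lesions grow from a field-weighted seed voxel by stochastic
6-connected dilation to an exact target voxel count, giving irregular but
connected blobs. Cohort marginals emulate the study population the pipeline
targets: 396 GBM / 190 LGG by default, male fraction 0.54, ages N(60, 13)
(GBM) / N(43, 14) (LGG), KPS N(82, 14) clipped.

The toy brain is ~10× smaller than an adult brain, and scale-dependent
defaults follow that geometry: lesion volumes are log-normal with median
~2.7 cm³ (~2% of the toy brain, as a ~30 cm³ glioma is of a real brain),
and the default log-hazard slope on periventricular distance is −0.10/mm —
the toy distance spread (~3 mm SD) is ~2.5× narrower than the real ~8 mm
SD, so a per-mm slope representing a moderate real-scale effect scales up
accordingly. Survival is exponential with log-hazard linear in (volume,
periventricular distance, age) around toy-scale reference values plus a
grade offset (median 14 months GBM, 40 LGG); exponential hazards keep the
model analytically transparent (a Weibull shape is a config extension).
Censoring is independent: each patient is censored with the configured
probability at a uniform fraction of their event time. A configurable
ventricle bias multiplies the GBM seeding field by exp(−β · SVZ distance),
reproducing the closer-to-ventricle GBM phenotype.

Expression matrices plant `n_assoc` genes as effect · z(frequency) plus
noise; the remaining genes are region-level Gaussian noise smoothed over
the centroid-distance kernel (so naive permutation nulls would be invalid,
which is the point); columns are z-scored. Receptor maps use a Gaussian
copula: frequency ranks → normal scores, mixed at the Pearson level
2·sin(π·ρ/6) so the Spearman correlation hits the target within ~0.1 at
R ≥ 100.

What the generator does not emulate: MRI intensities and segmentation
error, registration distortion, multifocal or infiltrative growth,
scanner/site heterogeneity, realistic gene-gene covariance, or
non-exponential survival. Passing tests therefore demonstrate that the
pipeline recovers structure of the kind it assumes, at desk scale — not
that the biological findings themselves reproduce.

## Validation studies and problem sizes

`gliomap.experiments` packages the studies run by the test suite and
`scripts/acceptance.py`, at sizes chosen for a single CPU: maxstat VLSM
familywise error over 200 null worlds (16³ grid, n = 60, 200 permutations;
observed ~0.05–0.06); spin and enrichment p uniformity over 200 re-drawn
null worlds (100 surrogates each); log-rank null rejection over 500
replicates at group size 75 (the χ² approximation is visibly inflated below
~25 per group, so null checks use quartiles of n = 300 cohorts); planted
recovery — ROI1 vs a planted blob (Dice ~0.95 at n = 300), planted genes
(median loading rank in the top 5%, set q < 0.05, spin p < 0.05), quartile
log-rank power > 0.8 at n = 300 under the default hazard coupling, and SVM
AUC > 0.65 under a strong planted mortality effect (log-hazard slopes
volume 0.3, distance −0.25, age 0.03: with exponential noise the
1-year-status Bayes AUC under the cohort-default slopes is only ~0.6, so
the recovery study plants the stronger monotone effect it is meant to
detect).

## Known limitations

- OS enters VLSM without censoring adjustment (as in common VLSM usage).
- Variogram-matching surrogates approximate, not reproduce, the map's
  spatial law; calibration was verified under the generator's conditions
  and may differ for maps with very different autocorrelation.
- The log-rank χ² approximation is anticonservative for groups ≲ 25.
- Risk-score coefficients are consumed as given; the package does not
  refit the Cox/LASSO model they came from.
- The chi-square helper is the uncorrected Pearson test (1 df) by design;
  Yates-corrected values will differ.
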