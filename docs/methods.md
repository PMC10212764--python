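# Methods

## Study design

The pipeline mirrors a two-stage multi-cohort design. A self-organizing map
is trained on cross-sectional data only: two survey-style cohorts with a wide
age range (25–74) and a birth cohort whose two fixed-age visits (31 and 46)
are first linearly interpolated to the target age 39, with weights
w_early = (46−39)/(46−31) = 7/15 and w_late = 8/15. The longitudinal cohort
(baseline ages 24–39, visits at +0/+6/+10 years) is then placed on the fixed
map using only its middle visit; the first and last visits never influence
the map or the subgroup boundary and therefore act as independent time
points. Subgroup boundaries are committed before any longitudinal modelling
— the pipeline enforces this ordering and records it in the run manifest.

## Synthetic data model

Each subject belongs to one of four latent subgroups g with configurable
proportions (default ¼ each). Two latent axes drive the panel:

* axis 1 (*divergence*): A₁ = b₁g·d + ω₁, with d = (age−24)/10 decades and
  per-subgroup slopes b₁g = (+0.35, −0.32, +0.05, −0.0082) SD/decade. All
  intercepts are zero: subgroups coincide at age 24 and separate with age.
* axis 2 (*progression*): A₂ = a₂g + b₂·d + ω₂ with stratified intercepts
  a₂g = (+0.2, −0.2, +1.0, −1.0) and a common slope b₂ = 0.37 SD/decade.

ω₁, ω₂ ~ N(0, 0.12²) are subject-level axis offsets shared across measures.

A measure is either **generic** — z = λ₁A₁ + λ₂A₂ + nuisance(age, sex) +
block noise + member noise — or **anchored**, with an explicit per-subgroup
(intercept, slope) table. The anchored table is needed because the published
LDL-C slopes (+0.46 High LDL-C vs +0.29 Low lipid) are per-subgroup values
that a single common-slope axis loading cannot express. Six measures are
anchored (insulin, triglyceride–cholesterol ratio, BMI, WHR, LDL-C,
glucose); the remaining 168 generic measures form 47 collinear blocks
(within-block correlation 0.85, axis-variance share 0.5 for loaded blocks)
so that the 174-measure panel collapses to 53 features after merging —
emulating the massive collinearity of an NMR metabolomics panel.

Variance bookkeeping: for every measure the systematic variance under the
longitudinal cohort's design (age moments in closed form) is subtracted from
1 and the remainder split into a subject-stable intercept and per-visit noise
by a per-measure ICC (insulin 0.60, LDL-C 0.70, WHR 0.75, BMI 0.85, glucose
0.65 — ten-year tracking correlations in the range reported for these
biomarkers). The pooled SD of each measure over the longitudinal cohort is
therefore ≈ 1, so a generative slope of b SD/decade is recoverable as a
standardized regression slope of b.

Natural scales: anchored measures map latent z to reported units via
x = center + scale·z, or exp(center + scale·z) for skewed measures. Two
calibration identities pin the anchors: the TG-rich BMI trajectory runs from
25 kg/m² at 24 to 30 kg/m² at 49 (scale 3.8 kg/m², slope 2.0 kg/m²/decade),
and the insulin log-scale SD is ln(3)/1.675 = 0.656 so that the model-implied
TG-rich : TG-poor ratio at 49 is exactly 3 on the natural scale. Insulin's
log-center ln(60) (pmol/L-like) keeps all generated values above 1, so the
robust log transform is an exact inverse of the generative map.

What the generator does **not** emulate: real NMR spectral noise and batch
structure, attrition that is informative about metabolic state (dropout is
optional and independent), genetic or lifestyle covariates, non-linear
trajectories, and the fuzziness of real subgroup membership (latent classes
are crisp here). Passing tests therefore demonstrate that the pipeline's
machinery is correct and well-calibrated under the declared statistical
structure, not that real cohorts satisfy that structure.

## Preprocessing

`standardize` computes empirical z-scores with two protections: measures
with |sample skewness| > 1 are log-transformed after an upward shift
max(0, 1 − min) that makes all values ≥ 1 (the shift is never downward — a
downshift of strictly positive data would destroy the log-linearity the
transform exists to exploit), and standardized values are clamped at ±4 SD.
The centre/scale are computed before clamping, so untransformed columns have
mean 0 and SD 1 up to clamping effects. Constant columns are dropped with a
warning. The full transform is recorded per column and re-applied verbatim
to new samples.

`adjust_covariates` residualizes each column on (intercept, age, sex) by
OLS — within each cohort when requested — and re-scales residuals to unit
SD; single-sex cohorts drop the sex term with a warning. `merge_collinear`
joins measures with |Spearman ρ| ≥ 0.8 by average linkage on 1 − |ρ|, and
each merged feature is the sign-aligned member mean, re-standardized. The
sign convention is the majority orientation (ties: first member in column
order); flipping any minority member leaves the feature unchanged. New
cohorts are processed in the order transform → stored-coefficient
adjustment → stored-membership merge, never refitted.

## Self-organizing map

Districts lie on a round lattice of concentric rings (ring k holds 6k
districts; 5 rings → 91 districts; a rectangular grid is available).
Training is the deterministic batch algorithm: all best-matching units
(BMUs) are found, then every prototype is replaced by the
Gaussian-neighborhood-weighted mean of the data. The radius shrinks linearly
from R/2 to 0.05, so the final epochs are plain Lloyd steps; an epoch's
update is accepted only if it does not increase the quantization error
(mean squared distance to the BMU), making the recorded per-epoch error
non-increasing by construction. Prototypes initialize from distinct data
rows chosen by the seed. BMU assignment uses Euclidean distance over
non-missing entries with ties to the lowest district id; training data are
column-mean imputed. District colorings are exact means (no spatial
smoothing), so the occupancy-weighted mean of district means equals the
overall mean to float precision; robustness is assessed by permuting values
across subjects with the add-one rule p = (1 + #{|perm| ≥ |obs|})/(n_perm+1).

## Subgroups

The human committee that drew the original boundaries is emulated by (a) a
user-supplied district→label JSON file, or (b) `auto_partition` — k-means on
the prototype vectors, optionally weighted by the projected cohort's
district occupancy, followed by a contiguity repair that absorbs every
disconnected fragment into the majority cluster of its lattice neighbors —
combined with a biochemical labelling rule: the region with the highest mean
triglyceride–cholesterol ratio is TG-rich, the lowest TG-poor, and of the
remaining two the higher-LDL-C region is High LDL-C, the other Low lipid.
Occupancy weighting matters because the training cloud is a fan (axis-1
spread grows over the surveys' 25–74 age range): unweighted k-means cuts the
long divergence ray into segments, whereas the boundary should partition the
region of the map where the projected population actually lives.

Subgroup profiles are means with percentile subject-bootstrap 95% CIs. The
prediction benchmark is stratified k-fold cross-validated multinomial
logistic regression (L2, C = 1); the random-label baseline repeats the CV on
permuted labels, and two biomarker panels are compared by a paired sign-flip
permutation test on fold-level accuracy differences (the original
comparison test is unpublished; this stand-in is documented as such).

## Trajectories

Age is centred at 24 and divided by 10, so the intercept is the expected
value at age 24 and β_age is per-decade; birth year enters centred. The
measure is standardized by the robust transform fitted on the pooled
longitudinal cohort (all visits, all subgroups) — a single population scale,
not per-visit. CIs resample whole subjects with all their visits (cluster
bootstrap, percentile method, default 2000 replicates). Slope divergence is
tested with the subgroup×age interaction F (full per-subgroup-slope model vs
common-slope model) against a null built by permuting subgroup labels at the
subject level; the analogous one-way F on subject means tests unadjusted
mean differences. Permutation p-values use the add-one rule, so the
smallest attainable p is 1/(n_perm+1); the default 9999 permutations give
resolution below the multiplicity threshold, while reduced counts used in
quick runs (e.g. 999) cannot clear it by construction. Curves are model
predictions over ages 24–49 with covariates at zero and bands from the
bootstrap replicates; standardized fits can be mapped back to natural units
through the stored transform. Quadratic/cubic age terms are deliberately not
implemented. Whether to bootstrap subjects or observations was an open
choice; subjects were chosen because repeated measures violate row-level
exchangeability.

## Multiple testing

The effective number of independent tests is the smallest k such that the
top-k eigenvalues of the covariance of the standardized (pooled, adjusted)
data reach the variance target (default 99%); the per-test threshold is
α/k. Covariance PCA is used, which coincides with correlation PCA for
unit-variance columns. The threshold only labels results tables as
significant or not; nothing is filtered.

## Problem sizes and runtime

The calibrated study uses the published cohort sizes (1286 longitudinal
subjects with three visits; 5304 + 4616 cross-sectional; 3117 birth-cohort
subjects) and runs in well under a minute on one CPU with reduced resampling
(200 bootstrap, 299 permutations); test-suite simulation studies use smaller
cohorts (40–100 subjects, 150–400 replicates) chosen so that Monte-Carlo
error is a fraction of the tolerance being asserted.

## Known limitations

* A design calculation (cluster-robust algebra, confirmed by simulation)
  shows the standardized-slope estimator has SE ≈ 0.05 SD/decade for the
  divergence measures at the published sample size — the residual variance
  is pinned at ≈ 0.89 once the printed slopes and the unit pooled SD are
  fixed — so single-cohort slope estimates scatter by about that much around
  the generative values; recovered values should be read with that
  uncertainty in mind.
* Subgroup recovery is imperfect near region boundaries for young subjects
  (the divergence axis has not yet separated them), attenuating divergence
  slopes by roughly 0.01–0.03 SD/decade.
* The committee emulation is a stand-in: the exact published boundary shapes
  and the exact merging/robustness internals of the original software are
  not reproduced, and the standardization's skewness cutoff (1.0) and
  clamping bound (±4 SD) are documented defaults rather than published
  values.
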