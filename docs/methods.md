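# Methods

`hnart` implements a two-part analysis for adaptive-radiotherapy (ART) triage
in head-and-neck (HN) cancer: (1) quantify the HN body volume on per-fraction
volumetric imaging and label each patient *reduction* / *non-reduction* by a
fixed rule, and (2) predict that label before treatment from clinical, dose
and radiomic features.  Because the clinical cohort this design targets is not
public, the package ships a synthetic generator whose geometry has closed-form
ground truth and whose feature tables have a declared effect structure; every
claim the test suite makes is therefore a claim about recoverability under
known conditions, not about any real cohort.

## Volume tracking

**Model.** The tracked quantity is the body volume between the C1 and C5
spinous-process levels, annotated once on the planning image.  For fraction
*n* with volume `V_n`, the change rate is the signed percentage

    dV_n = (V_n − V_1) / V_1 × 100 .

dV is kept signed even though the defining ratio is sometimes written with an
absolute value: the classification rule, and every summary statistic reported
with it, read "dV below −10%", which is meaningless unsigned.  No unsigned
mode is provided.

**Window mapping.** Couch-shift registration records map the planning-frame
C1/C5 positions into each fraction's image.  Only the axial shift component
moves the slice window; in-plane shifts move the crop box.  Positions are
quantized to 0.01 mm, the window is half-open `[c1, c5)`, and boundary slices
contribute pro-rata thickness.  A window that leaves the scanned range raises
an error — missing scan range is an exclusion, never an extrapolation.

**Segmentation.** Inside the crop box (which excludes the treatment couch and
immobilization hardware) the cropped window is thresholded with Otsu's method
by default; the value is configurable because acquisition intensity scales
vary.  Holes are filled per axial slice so internal air cavities (airways)
cannot deflate the volume, one 3-D binary closing with an in-plane 3×3
structuring element smooths the contour with the fewest free parameters, and
only the largest connected component is kept.  Volume is voxel count × pixel
area × slice thickness.

**Quality control.** A step of more than 5 percentage points in dV between
successive fractions flags the later fraction.  Flagged fractions are
re-segmented with alternative thresholds (recomputed Otsu, a fixed
mid-intensity fallback, then ±10% perturbations); the candidate that best
removes the local jump is kept, and dV is then recalculated for all fractions.
An empty segmentation (threshold above every body voxel) enters the same
repair path immediately.  The repair targets the flagged fraction, so a
corrupted *first* fraction — which shifts every dV — is outside its reach;
that limitation is inherent to a jump-based detector.

**Classification.** A patient is *reduction* when some run of three
consecutive fractions has mean dV ≤ −10%.  The mean-of-window form is used
(single-fraction estimates are noisy; averaging three suppresses that), with a
stricter all-three-below variant behind `rule="all"`.  The reported trigger is
the middle fraction of the first qualifying run — a run over fractions 24–26
reports 25.  The per-patient `min3_mean` (mean of the three most negative dV
values) is summarized per group as median and range.

## Synthetic imaging phantom

The phantom is a stack of axial ellipses — head wider than neck — on a
1×1 mm, 3 mm-slice grid, with a bright couch slab abutting the posterior image
edge, an optional interior air cavity, additive Gaussian intensity noise, and
per-fraction couch shifts drawn uniformly in ±5 mm per axis.  Axial shifts are
snapped to the slice grid because the slab body has no sub-slice structure;
the registration record stores the snapped value actually applied (fractional
axial arithmetic is exercised separately at the unit level).  Rotational setup
error is not simulated: the tracking design cannot correct rotation, so
simulating it would only add an error term no code path responds to.

Fraction *f* scales both in-plane semi-axes by `sqrt((1−s)^(f−1))`, so the
body volume decays exactly geometrically at rate *s* per fraction and
`Σ π a_i b_i t` gives an exact oracle at every fraction.  At the default
radii (≥ 30 mm) the voxelized body agrees with the analytic volume to well
under 2%.

Intensities are arbitrary units (air ≈ 50, tissue ≈ 1050, couch ≈ 1900,
noise SD 20): the target acquisition is stated only by tube settings, and no
per-fraction intensity distributions are available to calibrate against, so
only geometry is matched.  Default course length is 33 fractions (a 22 + 13
fraction two-phase course sharing one index set); the desk-scale demo uses 15.

**Cohort of phantoms.** Each patient's shrink rate is log-normal,
`s_i = s* · exp(σ(z_i − z_q))` with `z ~ N(0,1)`, where `s*` solves the
classification rule exactly (the rate at which the mean of the last three
relative volumes equals 0.9) and `z_q` is the population quantile at
1 − prevalence.  Crossing the rule threshold therefore has probability
exactly 0.29 by construction — the latent-severity-thresholded-at-the-top-30%
design — and the measured prevalence fluctuates binomially around it.
σ = 0.5 gives a plausible spread of course trajectories; the generator matches
the *prevalence*, not the full distribution of per-patient minima, which would
require a mixture the available summaries cannot identify.

## Feature metrics

**ICC robustness.** Radiomic features are screened by the two-way
mixed-effects, absolute-agreement, single-measure intraclass correlation
(McGraw & Wong Case 3A):

    ICC = (MS_R − MS_E) / (MS_R + (k−1) MS_E + (k/n)(MS_C − MS_E))

over n subjects × k repeated segmentations.  Single-measure form is
implemented (the average-measure alternative is noted as a design choice, not
a claim about any published pipeline).  Only features with ICC **strictly**
above 0.7 survive.  A zero-variance matrix returns 0 with a degenerate flag —
a constant feature is uninformative and should be dropped, not NaN-propagated.
The implementation is validated against an explicit ANOVA mean-squares
decomposition and against `pingouin`'s ICC(A,1).  Multi-rater inputs are
produced synthetically (contour erosion/dilation of phantom masks, or
feature-plus-rater-noise matrices); the ICC arithmetic is independent of how
the raters arose.

**GLCM / IMC1.** The one natively implemented texture feature is the first
informational measure of correlation,

    IMC1 = (HXY − HXY1) / max(HX, HY) ,

with all entropies in bits (log2), on a symmetric, normalized co-occurrence
matrix quantized to 16 equal-width levels by default.  IMC1 ≤ 0 always; 0
means the two gray levels in a pair are independent, and values toward −1 mean
stronger dependence, i.e. greater textural complexity.  The degenerate
constant-image matrix returns 0 by convention.

**DVH.** `dose_at_volume(d, x)` is the minimum dose received by the hottest
x% of equal-volume voxel samples (D2% ≈ near-maximum, D98% ≈ near-minimum),
computed by order statistic, hence exactly monotone non-increasing in x.

## Feature selection

Four filter selectors rank features for the binary label:

- **chi-square** — Pearson statistic of the 4-quantile-bin × class table;
  discrete features use native categories; constant features score 0.
- **MRMR** — greedy forward selection with the mutual-information-difference
  criterion `I(f;y) − mean_s I(f;s)`; MI is the plug-in estimate on 4-bin
  quantile codes, in nats.  The variant and estimator are canonical-filter
  defaults; nothing finer is specified by the design this mirrors.
- **NCA** — per-feature weights by gradient ascent on the leave-one-out
  soft-neighbor objective with L2 penalty λ = 1/n, weighted-Manhattan
  distances, kernel width fixed to the mean initial distance, step 0.1 with
  adaptive halving, 100 iterations, seeded near-unit initialization.
- **ReliefF** — the standard binary-classification generalization of relief:
  k = 10 nearest hits and misses per instance, all instances (no sampling, so
  deterministic), scores normalized by feature range and n·k.

NCA and ReliefF require z-scored input (NCA rejects anything else); the
dispatcher standardizes.  Categorical clinical factors are one-hot encoded at
generation time so distance-based selectors see them on a comparable scale.
Ties everywhere break by original column order and are recorded in the
ranking.  Patients missing a whole radiomic structure (only-GTVp or only-GTVn
cases) are median-imputed with one missingness-indicator column per structure;
complete-case analysis is available behind `impute="complete"`.

## Synthetic feature tables

The cohort generator emits 172-patient-style tables: 16 clinical columns with
marginals modeled on a published HN cohort profile, nine dose columns
(D2/D50/D98 × GTVp/GTVn/PTV) that are near-constant across patients —
optimizer constraints leave little between-case dose variation, which is
exactly why dose parameters should never win selection — and 107 radiomic
columns per structure drawn in AR(1) blocks (ρ = 0.6, width 10).  Correlated
blocks matter: with independent noise, MRMR's redundancy term would never
engage and the selector comparison would be vacuous.

Three columns carry signal: a GTVp IMC1-like feature with group means −0.35
(reduction) vs −0.47 (non-reduction), HPV16 positivity, and chemotherapy.
The IMC1 group means are fixed study-reported values; the conditional rates
for HPV (0.70 vs 0.12) and chemotherapy (0.92 vs 0.40) and the IMC1 SD (0.09)
are generator choices.  They are set strong enough that the three informative
columns separate reliably from the maximum spurious association among ~220
null columns at n = 172 — the regime the selector-recovery tests are about —
and that is deliberately stronger than the weak associations a real cohort of
this size exhibits; the resulting marginal rates (HPV ≈ 29%, chemotherapy
≈ 55%) drift accordingly from the clinical profile.  Passing recovery tests
on these tables shows the selectors find signal of this magnitude; it does
not show a real 172-patient cohort contains such signal.  `null_mode=True`
severs all three effects for calibration tests.

## Model evaluation

Outer 5-fold stratified CV estimates generalization; within each outer
training pool an inner 5-fold stratified CV grid search maximizes mean
balanced accuracy `((TP/(TP+FN)) + (TN/(TN+FP))) / 2`; ties keep the first
grid point in canonical (itertools-product) order.  The stated inner scheme
("five-fold among the remaining four parts") is arithmetically ambiguous;
pooled inner stratified 5-fold is the implemented reading.  The tuned model
is refit on the outer-training pool and scored on the held-out fold: AUC by
the rank (Mann–Whitney) statistic with half-credit ties, and accuracy /
sensitivity / specificity from hard labels (RF thresholds positive-class
probability at 0.5; SVM uses its zero-margin prediction, with raw decision
values for AUC — AUC is rank-based, so calibration is irrelevant).

Grids: RF criterion ∈ {gini, entropy} × depth 3–11 × trees
{10, 50, 100, 500, 1000, 2000}; SVM C ∈ {1, 10, 100, 1000} × kernel
{linear, rbf, poly, sigmoid} × gamma {0.001, 0.0001}.  The printed ranges are
discretized at these canonical points.  A coarse `HyperGrid.reduced()`
(same axes, fewer points) serves desk-scale sweeps.

The feature count is swept over 1–10 per (feature set × selector ×
classifier) cell; the **representative model** is the count with the highest
mean AUC, ties to fewer features, chosen globally (not per fold).  Feature
ranking happens per outer fold by default (`leak_free`); `paper` mode ranks
once on the full dataset, reproducing the internal-validation shortcut and
its positive bias, which the tests measure rather than hide.  The full grid
is 7 feature sets × 4 selectors × 2 classifiers = 56 representative reports.

Classifiers are consumed through fit / predict / score only, so the sklearn
implementations stand behind a two-method surface; everything around them
(folds, tuning loop, metrics, sweeps) is native.  The SVM estimator
standardizes its input internally (fit on whatever data it is trained on, so
inner-CV folds see only their own statistics) and caps libsvm at 2×10⁵
iterations: margin solvers are scale-sensitive, and large-C cells on the
near-constant dose columns otherwise fail to converge in any useful time.
Random forests are scale-invariant and consume features as-is.

## Problem sizes and numerical choices

Defaults were chosen so a full synthetic study runs on a single CPU in
minutes: phantoms are 18 slices × 104 × 96 at 1×1×3 mm with body semi-axes
30–40 mm (≈ 0.16 L — a deliberately desk-scale neck, not anatomical scale);
acceptance-style cohort runs use 172 patients × 33 fractions; grid sweeps at
n = 200 use the reduced grid and feature counts {1, 5, 10}.  The `run --demo`
pipeline uses 60 patients × 15 fractions.  Scaling any of these up changes
cost, not code paths.

Other fixed choices: 0.01-mm position quantization; Otsu on the cropped
window only (the couch would otherwise dominate the histogram); seeds derived
from a single run seed everywhere, with sklearn estimators seeded from the
same stream; MI and chi-square bins at 4 (quartiles — coarser is lossy,
finer is empty at n ≈ 170).

## Known limitations

- The phantom has no anatomy (bone, airway geometry beyond one cavity,
  immobilization mask contact) and no rotational or deformable setup error;
  tracking accuracy on it bounds algorithmic error only, not clinical error.
- The feature generator's informative effects are calibrated for testability
  (see above); absolute AUCs on synthetic tables are not comparable to
  clinical AUCs.
- The QC repair cannot recover a corrupted first fraction.
- ICC robustness screening uses synthetic rater variation; it validates the
  filter's arithmetic and wiring, not any dataset-specific robustness claim.
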