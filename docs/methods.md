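# Methods

## Problem and scope

The package predicts grade ≥ 2 radiation dermatitis (RD 2+) before breast
radiotherapy from three predictor families: clinical/dosimetric variables,
and radiomics features extracted from six dose-gradient regions of the
planning CT — PTV sub-volumes receiving ≥ 100/105/108% of the prescription
and skin sub-volumes receiving ≥ 20/30/40 Gy. Because no patient data are
deposited, every claim is exercised on a synthetic phantom cohort whose
generator is itself first-class, tested code.

## Synthetic cohort model

**Geometry.** Body = elliptic thorax section ∪ half-ellipsoid breast on a
64×64×40 grid at 4×4×5 mm (desk scale yet large enough for non-trivial
shape features). Skin = outer 5 mm layer of the body (distance-transform
threshold); PTV = breast tissue with that layer eroded away. Fractional-
millimetre morphology uses Euclidean distance transforms with physical
sampling, so the masks are spacing-aware.

**Dose.** Prescription plateau (50 Gy) inside the PTV, exponential falloff
exp(−d/λ) with distance d outside (λ = 25 mm × patient-level lognormal
jitter), plus a Gaussian hot spot (σ = 15 mm) centred on a random PTV voxel
with amplitude drawn from U(9%, 11%) of the prescription — guaranteeing the
in-PTV maximum is ≥ 108% so all six isodose ROIs are non-empty. Only the
ordering of isolines matters downstream; no treatment-planning physics is
claimed.

**Texture signal.** Soft tissue is 40 HU plus 5 HU white noise plus a
spatially correlated Gaussian random field (Gaussian-filtered white noise,
normalised in-region). The breast/PTV tissue and the skin shell carry
*independent* fields; for an RD 2+ patient both the field amplitude
(σ = 12 HU baseline) and its correlation length (6 mm baseline) are scaled
by (1 + δ) and (1 + δ/2) respectively, with per-patient lognormal spread
(SD 0.25 on the log) so that classes overlap. Independence of the two
regional fields reflects the workflow's multi-region premise: skin and PTV
texture are each informative and not mutually redundant. δ = 0 makes image
statistics identically distributed across classes by construction. The
default δ = 1 is the "strong planted signal" study condition: class texture
SDs differ by a factor 2, about 2.8 patient-level log-SDs apart.

**Clinical table.** 29 variables sampled from the published cohort's
per-class marginals pooled with weights 70:144, hence independent of the
label by default; an optional log-odds tilt (default off) can associate
Hormone therapy, T stage and Quadrant position with the outcome. Dosimetric
summaries (PTV/skin dose statistics, V20/V30/V40) are sampled from the same
table rather than recomputed from the phantom dose, keeping the clinical arm
label-independent.

**What the generator does not emulate:** real anatomy (lungs, chest-wall
layers), CT acquisition physics, inter-centre scanner differences (no
harmonisation such as ComBat is modelled), respiratory motion, and genuine
biological coupling between clinical covariates and toxicity. Passing tests
therefore demonstrate that the *pipeline* recovers planted image signal and
stays calibrated under the null — not that the radiomics signature exists in
real patients.

## Feature bank (884 per ROI)

Family allocation: GLCM 2.5D 22 × 8 directions × 4 offsets (1, 4, 7, 10) =
704; GLRLM 2.5D 11 × 4 directions = 44; NGTDM 2.5D 5; intensity-direct 56
(21 global + 7 local statistics × 5 aggregates over 3×3×3 in-mask windows);
intensity-histogram 40 (19 fixed quantiles + 21 summaries); Gaussian
mixture fits to the intensity histogram 18 (mean/SD/amplitude × 1-, 2-,
3-component fits, components sorted by mean); shape 17. "2.5D" means
matrices are accumulated per axial slice before statistics are computed.
GLCM matrices are symmetrised, so opposite directions (e.g. 90° and 270°)
yield identical values; both are emitted deliberately and the correlation
filter removes the redundancy downstream, mirroring a bank that enumerates
all eight directions.

Numerical conventions fixed for exact testability: min–max discretisation
into 64 gray levels (level 1..G; constant region → level 1); quantiles by
linear CDF interpolation (R type-7); SD/variance with ddof = 1;
entropy/uniformity on 64-bin (global) or 32-level (local window)
histograms, base-2 logs; NGTDM coarseness capped at 10⁶ for homogeneous
regions (1/0 guard); empty or sub-27-voxel ("degenerate") ROIs yield nulls
for all 884 features rather than failing, feeding the null-handling stage.
Texture matrices that cannot be formed (e.g. an offset exceeding the ROI
extent in every slice) yield nulls for that parameterisation only — on the
phantom this reproduces the realistic pattern where thin skin shells and
small hot-spot ROIs lose their long-offset GLCM columns.

Shape conventions: surface area from a marching-cubes mesh of the padded
mask; Max3DDiameter and MeanBreadth from the convex hull of voxel centres
(mean caliper width over 100 Fibonacci-sphere directions); convex
deficiency = (V_hull − V)/V_hull; roundness = equivalent-sphere diameter /
Max3DDiameter; orientation = polar angle of the first principal axis.

## Preprocessing

Continuous clinical nulls: iterative regression imputation under a
multivariate-normal working model (tolerance 1e-6, ≤ 100 sweeps; exactly
reproduces linear predictions under perfect collinearity). Categorical
nulls: chained-equation MI — multinomial-logit draws (m = 5) combined by
modal value, marginal-mode fallback. Observed cells are never altered;
fully-null or ≥ 50%-null columns are rejected.

Radiomics nulls: any column containing a null is dropped (the bank is
highly redundant and the null fraction low), with a per-ROI retention
report.

SMOTE: synthetic minority rows x + u(x_nn − x), u ~ U(0,1), neighbour drawn
among the k = 5 minority nearest neighbours in min–max-scaled Euclidean
space (raw radiomics scales would let single features dominate distances);
synthesis in the original space, integer-coded categoricals rounded back.
The default oversamples by whole multiples of the minority class (classic
"magnification" semantics — 70 minority rows double to 140); an exact-target
mode synthesises to round(ratio × majority) instead. Neither k nor the
distance metric is prescribed by the source workflow; both defaults are
declared, not inferred. SMOTE is applied to the full dataset *before*
splitting by default — faithful to the emulated workflow but optimistic,
since synthetic rows reach validation sets. `leakage_safe=True` instead
nests the *entire* supervised chain — clinical pre-screen, SMOTE and the
screening cascade — inside each training split, leaving validation rows
untouched originals the selection never saw; empirically, nesting SMOTE
alone still leaves null-cohort validation AUCs around 0.6–0.75 because
feature selection on the full data is itself a leak. The nested mode is
used for null-calibration checks, where honest validation is the point of
the exercise.

## Screening cascade

Fixed order, each stage only shrinks the set, every drop recorded with its
statistic in a replayable report:

1. Mann–Whitney U, two-sided normal approximation with tie correction,
   keep p < 0.05 (constant features get p = 1).
2. Variance > 0.05 computed on a min–max-scaled copy (a raw-scale threshold
   would delete nothing from HU-scale features).
3. Pairwise |Pearson r| ≥ 0.9 processed in descending |r| (ties by name);
   the member with the smaller |point-biserial correlation to the label| is
   dropped.
4. Iterative VIF: remove the max-VIF feature while any VIF ≥ 10; exact
   collinearity is treated as infinite VIF.
5. Wrapper (encapsulation) selection: backward elimination guided by
   out-of-bag permutation importance of a bagged regression-tree forest
   (500 trees by default; depth 6, √p feature subsampling), eliminating 10%
   of features per step, with stratified 5-fold CV AUC recorded at every
   size; the subset of size ≤ 20 maximising mean CV AUC wins, ties to the
   smaller subset. `force_k` pins the returned size; a step fraction of 0
   disables elimination. Full-cohort pipeline runs use 150 trees and a 20%
   step — problem sizes chosen to keep a complete run at desk scale while
   leaving the selection behaviour unchanged.

The clinical arm is pre-screened by univariate p < 0.5 (strict), then
summarised by multivariable logistic regression (Newton–Raphson, tol 1e-8,
≤ 50 iterations, Wald inference, separation detection). The permissive 0.5
threshold deliberately over-includes candidates.

## Boosting model

Binary GBDT with the Bernoulli loss written as L(y, f) = log(1 + e^(−y f))
for y ∈ {−1, +1} — note there is no factor 2 in the exponent, so
p = 1/(1 + e^(−f)). Initial score f₀ = log(n⁺/n⁻) (clamped at ±10 if a
class is absent); residuals r = y/(1 + e^(y f)); depth-3 regression trees
(min leaf 5) fitted to r by exhaustive squared-error splits with
deterministic tie-breaks (lower feature index, then lower threshold); leaf
updates by the closed form c = Σr / Σ|r|(1 − |r|) (zero when the
denominator underflows, capped at ±10³); shrinkage ν = 0.05. The shrinkage
multiplies every leaf update even though the classic pseudocode omits it —
the stated parameter governs. The useful iteration count M* minimises mean
held-out Bernoulli deviance over 5 internal stratified folds. Variable
importance is split-gain (squared-error improvement) accumulated per
feature and normalised to percent; partial dependence clamps one feature
across a grid and averages the decision score. Desk-scale default is
M = 500 trees; `--paper-scale` raises it to the published M = 10000.
Bagging is off by default (bag fraction 1), making training deviance
provably non-increasing.

## Evaluation

Five independent stratified 70/30 train/validation splits of the (balanced)
dataset; the literal "five disjoint sub-folds each split 70/30" reading is
available via `SplitScheme(per_subfold=True)`. 70/30 is the governing
fraction (one passage of the source text says 75/25; the Methods value
wins). AUC is the normalised Mann–Whitney U with ties counted ½ — by
construction identical to the U statistic the screening filter uses. CIs
are Wald intervals on the fast structural-component (DeLong) variance,
truncated to [0, 1]. Validation rows never intersect training rows; with
SMOTE-before-split the caveat above applies and is surfaced in the report.

## Design choices on genuinely open points

- "Decision-tree encapsulation screening" is operationalised as
  random-forest backward elimination (the forest is configurable down to a
  single tree), reconciling the tree-based and forest-based descriptions of
  the same step.
- The univariate-p < 0.5 clinical pre-screen does not, on the published
  table, reproduce the published 8-variable regression roster; the
  implementation applies the stated rule and accepts an explicit
  include-list override rather than guessing intent.
- Skin isodose thresholds use physical Gy (not EQD2); thresholds are
  inclusive; dose is always resampled onto the image grid, never masks.
- Voxel centres follow the ITK convention (origin + index × spacing).
- The histogram family pads its stated statistics with plain variance to a
  round 40; the bank total of 884 is preserved by the family allocation
  above.

## Known limitations

- Feature definitions follow standard formulations (Amadasun–King NGTDM,
  Galloway/Chu GLRLM, Haralick-style GLCM) with the conventions pinned
  above; bit-compatibility with any specific radiomics program is not
  claimed.
- Null calibration is an aggregate property, not a per-cohort one:
  conditional on a single finite cohort, chance associations among the 29
  label-independent clinical covariates are shared by every train and
  validation split drawn from it, so even the fully nested evaluation can
  report clinical-arm validation AUCs of 0.6–0.7 on an unlucky cohort.
  Regenerating cohorts restores calibration (validation AUCs scatter around
  0.5 with near-nominal CI coverage). The same conditioning caveat applies
  to any single-cohort study of this design.
- r×k contingency tables failing the chi-square condition use a seeded
  Monte-Carlo conditional test (2000 permutations) rather than the exact
  network algorithm.
- Gaussian-mixture histogram fits can legitimately fail to converge on
  small ROIs; they return nulls and flow through the null-handling path.
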