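# Methods

This note documents the models implemented in `brainsim`, the choices made
where the design was genuinely open, and what the synthetic cohorts do and
do not establish about real data.

## Perturbation-based individual similarity networks

The normative (reference) structural covariance network is the matrix of
partial Pearson correlations r_ij between the cortical thickness of region
pairs (i, j) across an amyloid-negative reference group, controlling for
age, sex and education. Partialling is implemented as
residualize-on-covariates followed by plain Pearson correlation of the
residuals, which is algebraically the partial correlation with respect to
those covariates. We deliberately do **not** partial on the remaining
regions (precision-matrix partialling): the covariates to be removed are
demographic, not network-internal.

A subject's individual similarity network is obtained by appending that
subject's thickness row (with their covariates) to the reference data,
recomputing the partial-correlation network with the identical adjustment,
and subtracting the reference network. The resulting difference matrix is
z-scored *within subject* over the 2278 (for 68 regions) upper-triangle
edges: the z-matrix has mean 0 and SD 1 off-diagonal by construction, with
the diagonal excluded and set to 0. An across-subject per-edge
standardization would be the alternative reading; within-subject
standardization is used because the z score is defined over the entire
network of one individual. Every visit of a subject perturbs the same fixed
baseline reference network, since the norm is defined once from baseline
reference data.

Two properties follow and are enforced by tests: (i) the difference matrix
of a subject drawn from the reference distribution shrinks as O(1/n) with
reference size; (ii) with n = 114 reference subjects, a subject duplicating
an existing reference member changes no edge by more than 0.05.

### Reference-size stability

Subsets of the reference group are drawn *without replacement* over a grid
of sizes (1000 resamples per size by default), the network is rebuilt per
subset, and its upper-triangle edge vector is compared to the full-sample
network using the intraclass correlation coefficient in its two-way mixed,
single-measure, consistency form, ICC(3,1) = (MSR − MSE)/(MSR + MSE) for
two raters. Consistency (rather than absolute agreement) is the right form
because a uniform additive bias in a subset's correlations should not count
against reliability. The smallest grid size whose mean ICC exceeds 0.75 is
reported as the minimally reliable reference size.

## Longitudinal screening model

For each candidate feature x (a similarity edge, a regional thickness, a
volume, or a baseline fluid biomarker) and each cognitive outcome y
(z-scored; TMT-A, TMT-B and ADASQ4 inverted first so higher = better), we
fit by maximum likelihood

    y_it = β0 + β1 x_it + β2 t + β3 (x_it · t) + γ·covariates + u_i + e_it,

with a per-subject random intercept u_i ~ N(0, τ²) and residual
e ~ N(0, σ²). Covariates are age, sex and education, plus total
intracranial volume for volumetric predictors. Baseline-only predictors
(fluid biomarkers) enter as time-constant values interacting with time.
The screening statistic is the Wald test of β3, the feature-by-time
interaction. ML (not REML) is used throughout so that log-likelihoods are
comparable across fixed-effect specifications, which the nested comparisons
require.

### Fitting

The random-intercept model admits an exact profiled likelihood: for
ψ = τ²/σ² the per-group marginal covariance is σ²(I + ψJ), whose inverse is
I − ψ/(1 + ψn_g)·J, so GLS estimates, the profiled σ², and the profile
log-likelihood are closed-form given ψ, leaving a one-dimensional smooth
maximization (with the ψ = 0 boundary checked explicitly). This dedicated
fitter is used because edgewise screening, null calibration, and the
nested-comparison stage need tens of thousands of fits; it is exact ML for
this model and agrees with `statsmodels.MixedLM` to optimizer tolerance
(asserted in the test suite, which keeps the general-purpose implementation
as an independent oracle rather than the production path).

Wald inference uses a small-sample correction: the residual variance is
rescaled by n/(n − p) and the reference distribution is t with n − p
degrees of freedom. The ML plug-in variance with a normal reference is
anticonservative in the far tails at screening scale (tens of subjects,
hundreds of simultaneous tests sharing one FDR family), which inflates the
family-wise false discovery rate; the correction restores control (checked
by a 190-edge global-null simulation).

### Multiplicity

Benjamini–Hochberg FDR at α = 0.05 is applied **within** each family
defined by marker type × outcome × group — similarity edges, thickness
regions, volumes, and fluid biomarkers each get their own correction.
Features whose fit fails (degenerate predictor, collinearity) are excluded
from the family size with a logged warning. We report the Nakagawa–
Schielzeth marginal R² (fixed-effect variance over total variance) for each
fit, with the conditional R² (adding τ²) alongside, because the R² variant
used in comparable analyses is typically unstated; the marginal form is the
one that reflects the predictor's explanatory power.

## Nested pairwise comparison

To ask whether marker A carries predictive information beyond marker B, for
every pair (a, b) of screening-significant features three models are fit on
identical rows: a-only, b-only, and a full model with both predictors and
both predictor-by-time interactions (shared covariates). Two likelihood-
ratio tests per pair (df = 2 each: the added main effect and its time
interaction) are BH-corrected within the comparison family; "A wins the
pair" means the full model significantly improves on the b-only model. Win
frequencies across pairs form a 2×2 wins/non-wins table tested by
chi-squared, or by Fisher's exact test (reporting the odds ratio) whenever
any expected cell count is below five.

The 2×2 construction (wins vs non-wins per marker over the same pairs) is
one of several defensible readings of "comparing the frequency of wins";
it is a documented choice, and the summary test should be read as a
heuristic: win indicators across pairs that share features or data are not
independent, so its p-value is exact only when pairs are effectively
independent. The calibration test therefore uses independent replicate
cohorts per pair, with both markers carrying equal true effects (the actual
null hypothesis of the summary test — "pure noise" markers produce no wins
at all and the test degenerates).

## Conversion classification

Per marker type, an L1-penalized logistic regression selects features: the
penalty grid has 50 log-spaced values from λ_max (the smallest penalty that
zeroes every coefficient, max|X'(y − ȳ)|/n on standardized features) down
four orders of magnitude, and λ is chosen by minimal mean 5-fold
cross-validated binomial deviance. Selected features enter an unpenalized
logistic classifier evaluated by 1000 bootstrap iterations of stratified
80/20 train/test splits; each iteration contributes an ROC curve
interpolated onto a fixed 101-point FPR grid. We report the pointwise
median curve, its 2.5/97.5 percentile band, and the median AUC with IQR.

Selection runs once on the full sample before the bootstrap, mirroring the
sequence "select, then classify"; this is optimistic because the test folds
have participated in selection, and an inside-the-loop mode
(`select_within_loop=True`) is provided for unbiased estimates. Splits are
stratified by label to avoid degenerate test folds at small n. At the
default desk scale (30 target subjects) the minimal-deviance rule
legitimately returns an empty selection for some datasets — label noise can
dominate 6-subject test folds — in which case the classifier falls back to
intercept-only scores (AUC 0.5) with a logged warning rather than
fabricating a model.

## Cytoarchitectural mapping

Desikan–Killiany regions are grouped into the seven von Economo–Koskinas
cytoarchitectural classes (PMC, PSC, SSC, AC1, AC2, LIMB, INS). The
34-row region→class table ships as an editable CSV asset
(`brainsim/data/dk68_von_economo.csv`), assembled from the standard
literature assignments of DK parcels to von Economo types and mirrored
bilaterally; no authoritative per-region table exists in a single printed
source, so all class-level results are parameterized by this file.

Two statistics summarize significant similarity edges: the inter-regional
similarity proportion (percentage of significant edges per unordered class
pair; sums to 100% over unique pairs) and the regional contribution
(percentage of edge *endpoints* per class; a within-class edge contributes
both endpoints, so the 7-vector sums to 100% exactly). The endpoint
denominator (2 × edges) is a reconstruction chosen because it guarantees
the printed-percentage identity even when within-class edges exist.

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes, at
ADNI-like magnitudes by default: 114 reference, 26 incident and 45 elevated
amyloid-positive subjects, 68 regions, three annual visits; age ~
N(71, 8²) truncated to [55, 95] years, education ~ N(16, 3²) truncated to
[8, 22] years, sex Bernoulli(0.5). Thickness is multivariate normal
(mean 2.5 mm, SD 0.12 mm) around covariate effects, with a correlation
matrix organized in seven community blocks sized proportionally to the
cytoarchitectural classes (within-block r = 0.5, between 0.15). Target
subjects draw from a covariance whose planted edges — a five-edge star
around an association-cortex hub — are shifted by −0.4 (×1.5 in the
elevated group, scaled per subject by a uniform exposure in [0.5, 1]),
re-projected to the nearest PSD correlation matrix by eigenvalue clipping
at 1e-8. The hub-star topology makes the planted edges co-vary, emulating
focal disconnection of a hub region.

The **deviation score** that drives cognition and conversion is, by
default, the subject's *measured* similarity deviation: the negated mean z
value over the planted edges of their own perturbation network against the
cohort's reference group (`deviation_mode="network"`). This makes "cognitive
slopes depend on similarity deviations" literally true in the generated
data. Two latent alternatives are available: the subject's planted-edge
product deviation (`"product"`), and the pure exposure × shift magnitude
(`"latent"`). The latent modes carry the same mean signal but are only
weakly recoverable from single-subject networks, because the realization
noise of one multivariate draw is O(1) at any reference size; this is an
informative fact about the method (single-subject similarity measures a
subject's realized configuration, not a latent trait) and is why the
measured deviation is the default ground truth.

Cognitive trajectories follow the screening model exactly (random intercept
SD 0.5, residual SD 0.25, population slope −0.05/yr, interaction −0.4 per
unit deviation per year) on a latent z scale mapped to each test's raw
scale, with TMT-A/TMT-B/ADASQ4 emitted so that higher raw = worse. Fluid
biomarkers are log-normal at cohort-typical medians with a +0.3 log-scale
shift in amyloid-positive groups plus a 0.25 log-unit per deviation link;
volumes and thickness carry a weak share of the disease process (focal
thinning of the perturbed regions, mild hippocampal/gray-matter loss), so
competing markers have genuine but inferior signal, as in the study design
being emulated. Conversion is Bernoulli with logit −1.5 + 8 × deviation —
a sharp link, because conversion diagnoses reflect sustained decline rather
than an independent noisy draw.

What passing tests show: the chain recovers planted covariance structure,
controls FDR, estimates interaction coefficients without bias, ranks an
informative marker above a noise marker, and classifies labels generated
from its own features. What they do not show: performance under real-world
violations — missing visits, site effects, non-Gaussian thickness
distributions, covariance structure that drifts with age, or markers whose
signal is not a linear function of a similarity deviation.

## Pipeline and problem sizes

`run_pipeline` executes simulate → cognition preprocessing → reference
network → individual networks → stability curve → screening (per marker ×
outcome × group) → nested comparisons → conversion classifiers (including
a combined similarity + fluid model) → cytoarchitectural summaries, writing
CSV/JSON artifacts and a manifest with SHA-256 content hashes. The default
synthetic configuration is desk-scale: 20 regions (190 edges), 60 reference
plus 30 target subjects analyzed as one pooled amyloid-positive group,
3 visits, 200 bootstrap iterations, 100 stability resamples — sizes chosen
so the full pipeline, test suite and acceptance script each run on a single
CPU in minutes while preserving every structural feature of the full-scale
analysis (the ADNI-scale defaults remain available through `SimConfig()`).
In the pairwise comparison stage the pipeline caps each marker's
significant set at the 10 smallest-q features to bound the number of model
fits; `compare_marker_pairs` itself is uncapped.

Numerical conventions: matrices are kept exactly symmetric (symmetrize then
mirror); z-standardization tolerances are 1e-10; LRT statistics are clipped
at 0 with a refit warning if the full model's log-likelihood falls below a
nested model's by more than 1e-6; eigenvalue clipping floor 1e-8; visit
alignment retains rows whose companion acquisitions fall within ± half the
6-month window of the scan date.

## Known limitations

- The summary chi-squared test over correlated pairwise wins is heuristic
  (see above); treat its p-value as descriptive when pairs share features.
- Full-sample LASSO selection before the bootstrap is optimistically biased;
  use the inside-the-loop mode for honest AUC estimates.
- The region→class table is an editable reconstruction, not a canonical
  published table; class-level percentages move if it is edited.
- No random slopes: heterogeneous trajectories beyond the planted
  interaction are absorbed into the residual.
- Missing data are handled by row-wise deletion only.
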