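# Methods

`lipidchemo` implements a discrimination workflow for replicated
untargeted LC–HRMS serum lipidomics: a case/control cohort (schizophrenia
patients, SCH, vs non-psychiatric controls, C) measured in triplicate
injections, analysed gender-stratified because gender structures the
control-class lipidome much more strongly than disease structures either
class. This note records the models, the defaults that matter, and the
choices made where the design was genuinely open.

## Synthetic cohorts

Real serum cohorts of this kind are not publicly sharable, so the
package carries a first-class generator whose defaults *are* the study
design the analysis assumes: 15 + 15 SCH and 16 + 15 C individuals by
gender (61 individuals), triplicate injections (183 chromatograms), 192
m/z(rt) features, 4 acquisition batches.

Intensities are log-normal with all effects additive on the log10 scale:

    log10 X_ijr = mu_f + delta_f·[SCH] + gamma_f·[F] + batch_b + u_if + e_ijr

with per-feature baselines `mu_f ~ U(4, 6.5)` (typical peak-intensity
decades), an individual-level biological deviation `u ~ N(0, 0.15²)`, an
injection-level technical deviation `e ~ N(0, 0.05²)` (so technical
replicates are ~3× tighter than biological spread, as replicate
injections of one extract should be), and batch shifts `N(0, 0.02²)` —
deliberately negligible, since the emulated study found no batch drift
and applied no normalisation.

Effect patterns, where the user supplies none, are sparse conventions
(the emulated study reports loading signs but no effect sizes): 40 of 192
features carry a disease shift of 0.3 log10 units, 70 % decreased in SCH
/ 30 % increased, matching the reported predominance of lipid depletion
in patients; 30 features carry a gender shift of 0.4 log10 units applied
**only within the control class** (`gender_effect_in_controls_only`),
reproducing the study's striking pattern of gender separation in C and
none in SCH. Missingness is completely at random (2 % by default; the
study does not characterise its mechanism). Gross outliers are injected
by multiplying a random half of a sample's features by 10^±2; the
study-design scenario corrupts 14 samples split 9 C-M / 1 SCH-M / 4
SCH-F, the split implied by the study's before/after arithmetic
(48→39, 45→44, 45→45, 45→41).

What the generator does **not** emulate: correlated lipid co-regulation
(features are independent given the design), heteroscedastic
detector noise, retention-time drift, informative missingness, and any
relation between a feature's m/z and its effect. Passing tests therefore
demonstrate that the algorithms recover planted structure of the assumed
form at realistic sizes — not that they would rank true lipids correctly
in a real cohort.

## Pre-treatment

Imputation runs on the raw intensity scale (before the log), column-wise
in acquisition order: linear interpolation of the neighbouring observed
values, with constant extension of the nearest value at the series
boundaries (the emulated study's account is silent on boundaries; nearest-value extension
is the least-assuming choice). `movemedian` (centred window of 3) and
column-median imputation are provided as the alternatives the study
compared. Then log10 (log2 available), then autoscaling (mean centre,
unit SD, sample SD with ddof = 1). Zero-variance features are dropped
with a warning rather than an error because synthetic null cohorts can
legitimately produce them. No between-sample normalisation is applied;
QC reliability is instead reported as intra-day (per-batch, pooled) and
inter-day coefficients of variation with a strict `CV < 30 %` pass flag.
Scaling parameters are frozen in a `ScalingModel` so held-out folds are
always scaled with training-fold statistics.

## Robust outlier map

The screen follows the ROBPCA recipe: SVD reduction to the affine span
of the data; Stahel–Donoho outlyingness maximised over 250 random
directions through data-point pairs (median/MAD scale); classical PCA on
the `h = ceil(0.75 n)` least outlying rows; one reweighting step that
refits on rows whose orthogonal distance falls under the cutoff. Each
sample then gets a score distance `SD = sqrt(sum_a t_a²/lambda_a)` with
cutoff `sqrt(chi²_{k,0.975})`, and an orthogonal distance (Euclidean
residual norm) whose cutoff applies the Wilson–Hilferty transform:
OD^{2/3} treated as normal with median location and 1.4826·MAD scale,
cut at the 0.975 quantile. The two cutoffs partition samples into
regular / good-leverage / orthogonal-outlier / bad-leverage.

Removal policy is configurable. `categorical` removes the two OD-outlier
categories; but with a 0.975 quantile roughly 2.5 % of perfectly regular
samples sit above the cutoff by construction, so the pipeline default is
`distinctive`: among above-cutoff samples, split at the largest gap in
sorted OD and remove only the detached cloud — the operational reading
of an analyst isolating "distinctive" outliers from the diagnostic plot.
On the study-design scenario this removes exactly the 14 corrupted
chromatograms (183 → 169) across every seed tested.

PCA component counts are chosen from scree eigenvalues and an
element-wise cross-validated RMSECV: held-out entries are predicted from
the *other* features of their held-out row via least squares on the
training loadings with that feature's row deleted, so an entry never
participates in its own reconstruction. The outlier screen uses k = 6
components by default, mirroring the exploratory model of the emulated
study.

## Feature ranking

The F-ratio filter is the per-feature one-way ANOVA statistic with
(g−1, n−g) degrees of freedom and the parametric upper-α critical value
(α = 0.05 default).

Random-Forest importance uses hand-rolled bagging over scikit-learn
decision trees (mtry = floor(sqrt(p)) features per split) so that the
out-of-bag set of every tree is explicit: Mean Decrease Gini is the
unnormalised impurity decrease per root sample, averaged over trees;
Mean Decrease Accuracy permutes each feature in the OOB set and averages
the accuracy drop.

Because triplicates would otherwise enter bootstraps unevenly, the
stability procedure draws **one random replicate per individual** before
each forest — every draw holds the same individuals, different
injections. B such forests (1000 by default; 100 trees each) yield B
Gini-importance ranking lists, summarised by rank-segment counts
(positions 1–5, 6–10, 11–15 inclusive) and aggregated by Borda count:
each feature scores the number of features ranked below it, summed over
lists, which is equivalent to ordering by average rank. Ties (exactly
equal Borda scores) break by mean rank and then feature index so output
is deterministic. Per-replicate seeds come from a spawned seed sequence.

Corrected Gini importance p-values: each of B rounds fits three forests
on the replicate-subsampled data — real labels, a fresh per-round label
permutation (baseline that removes the positive bias of impurity
importance), and one label permutation **frozen across all rounds** (the
null channel). The ensemble-mean real-minus-baseline importance is the
corrected importance; the frozen channel's corrected importances form
the null pool, and `p_j = (1 + #{null ≥ corrected_j})/(n_null + 1)`.
The more common mirrored-null construction (reflecting non-positive
corrected importances) was implemented first and measured to be
anti-conservative here — 9–16 % of pure-noise features below p = 0.05
across seeds — because a fixed label vector accumulates dataset-level
chance association over the ensemble with no mirrored negative
counterpart. The frozen-permutation channel is distributionally
identical to the real channel under the null by exchangeability, and
measures calibrated (type-I ≈ 5 %, KS-uniform).

## OPLS-DA

Class membership is coded 0/1 (C = 0, SCH = 1) and regressed on the
autoscaled matrix. "n components" means 1 predictive + (n−1) orthogonal
latent variables: a single-response OPLS model has exactly one
predictive direction `w ∝ X'y`, which is invariant under orthogonal
deflation, so orthogonal scores have exactly zero covariance with the
class code by construction. With n = 1 the model is identical to
single-component NIPALS PLS1 (verified to 1e-8 against an independent
implementation).

Validation preserves replicate groups everywhere. The outer partition
deals shuffled individuals class-by-class onto the currently smallest
fold (never splitting a triplicate), giving ~even fold sizes and class
balance within two groups. Each fold in turn is the prediction set; the
component count is chosen inside the calibration set by grouped
cross-validation as the argmin of RMSECV. Reported per fold: RMSECV,
RMSEP, R²cv, R²p — all R² as `1 − SS_res/SS_tot` on the coded response,
not squared Pearson correlations (the study does not say which it used;
this choice is the regression-consistent one) — plus accuracy and
misclassification for both calibration (cross-validated predictions) and
prediction.

The discrimination threshold is the equal-density point of per-class
Gaussian fits to the cross-validated predictions (equal priors): the
quadratic equal-posterior equation solved between the class means, which
reduces to the midpoint for equal variances and leans toward the tighter
class otherwise. The thresholds of the two complementary 0/1 codings sum
to 1 by construction, matching the complementary pairs the study prints
(0.4943/0.5057, 0.4242/0.5758). Degenerate classes fall back to the
mean midpoint, or 0.5 with a warning.

VIP over all components, `VIP_j = sqrt(p · Σ_a SSY_a (w_aj/‖w_a‖)² /
Σ_a SSY_a)` with SSY the class-code variation a component explains;
orthogonal components explain none, so the predictive weights dominate
and mean(VIP²) = 1 exactly, making VIP > 1 the above-average cutoff.

## Validation stage

Feature subsets are prefixes of a supplied ranking (the VIP ordering in
the pipeline). For each candidate size the grouped CV is refit from
scratch; the chosen size is the smallest whose RMSECV lies within one
standard error (per-fold RMSE spread at the minimiser) of the minimum —
the study's own subset-validation algorithm is not available in the provided
text, so this 1-SE prefix rule is declared as this package's procedure
and is pluggable. Permutation tests permute class labels **across
individuals** (replicates move with their individual; permuting within
replicate groups would not break the class structure and is rejected),
recomputing partition, CV, threshold and statistic per permutation;
`p = (1 + #{perm ≥ obs})/(B + 1)` with B = 999 default, so the smallest
attainable p is 0.001. Shared features between the two gender subsets
are the strict canonical-label intersection after trimming typographic
markup; chromatographic-variant suffixes ("A1", "B") are retained as
distinct features.

## Annotation

Neutral monoisotopic masses are summed from exact most-abundant-isotope
masses (C, H, N, O, P, S, Na, K); adduct m/z = multiplier × mass + an
electron-corrected delta ([M+H]+ 1.007276, [M+NH4]+ 18.033823, [M+Na]+
22.989218, [M+K]+ 38.963158, [M−H]− −1.007276, [M+OAc]− 59.013851,
[2M+Na]+ doubling the mass). Matching tolerance defaults to 10 ppm
(printed deviations in the transcribed tables run ~1–5 ppm); all
polarity-consistent (species, adduct) hits are returned sorted by |ppm|,
ambiguities included.

The bundled library transcribes the study's two differential-lipid
tables verbatim — 69 features / 49 molecules (male) and 74 / 60 (female)
— including printed inconsistencies, which are flagged `suspect=1`
rather than corrected (e.g. a formula implying a different species than
its name, and two rows whose printed adduct is inconsistent with the
printed m/z but whose species is recovered through another adduct of the
same polarity). The batch audit therefore asks the operative question —
does annotating the printed m/z at the printed polarity recover the
printed species within tolerance? — which succeeds for 95.1 % of rows;
the strict printed-(formula, adduct) ppm is reported per row as well
(93.0 % within 10 ppm, the misprinted rows accounting for the
difference). The transcription also carries 40 + 60 validated-feature
hash marks against the 41 + 61 the study's text states, an extraction
loss that shifts the shared-label intersection from the stated 23 to a
computed 21.

## Problem sizes and numerics

Stability ranking defaults to B = 1000 forests of 100 trees; the test
suite exercises the same code at B = 30–60 with 50–100 trees, sizes at
which the planted-feature top-segment concentration and cross-seed
aggregate overlap are already decisive. Permutation tests run at
B = 999 where the 0.001 floor matters and B = 19–99 in property checks.
The null-calibration study uses 50 independent 20-individual cohorts.
NIPALS-style computations are closed-form per component (no iteration
needed for a single response); PCA eigendecompositions use symmetric
`eigh`; random directions, bootstraps, subsamples and permutations all
derive from spawned `SeedSequence` streams so every result is
reproducible bit-for-bit from one master seed.

## Known limitations

- The generator's independence of features means covariance-driven
  phenomena (orthogonal variation with biological meaning, correlated
  VIP selection) are only weakly represented.
- ROBPCA's random-direction outlyingness is a Monte-Carlo approximation;
  flags are seed-stable but an adversarially small direction budget
  could miss structured outliers.
- The equal-prior Gaussian threshold ignores class imbalance in
  deployment populations.
- Annotation is accurate-mass only: no MS/MS evidence, isotope-pattern
  scoring or retention-time modelling, so hits are tentative by design.
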