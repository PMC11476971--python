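# lipidchemo

Chemometrics for case/control serum lipidomics fingerprints with
technical replicates.

Untargeted LC–HRMS lipidomics of psychiatric cohorts typically yields a
samples × m/z(rt) peak table in which every individual appears as
triplicate injections, gross outlier chromatograms must be screened out
before modelling, and — a pattern this workflow is built around — gender
structures the control-class lipidome far more strongly than disease
structures either class, so discrimination models are fit per gender.
`lipidchemo` implements that workflow end to end for analysts working
with such tables (and, because cohorts of this kind are rarely sharable,
ships a synthetic-cohort generator that reproduces their statistical
structure so every stage is testable offline):

- **robust outlier map** — ROBPCA-style robust PCA; per-sample score
  distance vs orthogonal distance with χ² / Wilson–Hilferty cutoffs and
  regular / good-leverage / orthogonal / bad-leverage categories;
- **stability feature ranking** — per-feature ANOVA F-ratio with a
  parametric threshold, plus Random-Forest importance (Mean Decrease
  Gini / Accuracy) refit on B replicate-aware subsamples (one random
  injection per individual per draw), rank-segment counts, and Borda
  aggregation (equivalent to mean-rank ordering);
- **OPLS-DA** — one predictive + (n−1) class-orthogonal latent
  variables fit NIPALS-style on the 0/1 class code; replicate-preserving
  5-fold validation with RMSECV/RMSEP, R²cv/R²p, Gaussian
  equal-posterior discrimination thresholds (complementary pair sums to
  1), and VIP scores (mean VIP² = 1, selection at VIP > 1);
- **validation** — 1-SE prefix subset selection over a ranking,
  individual-level permutation tests, cross-gender shared-feature
  intersection;
- **annotation** — exact monoisotopic masses, electron-corrected adduct
  m/z ([M±H], [M+NH4]+, [M+Na]+, [M+K]+, [M+OAc]−, [2M+Na]+), ppm
  matching against a bundled lipid library, and lipid-shorthand parsing
  (`Cer 34:1;O2 B` → class/carbons/double bonds/extra O/variant).

See `docs/methods.md` for the models, defaults and design choices.

## Worked example

Run the whole workflow on the default emulated design (61 individuals
in triplicate → 183 chromatograms × 192 features, 14 corrupted
injections):

```python
from lipidchemo.pipeline import PipelineConfig, run_pipeline

cfg = PipelineConfig(seed=1, ranking_B=200, permutation_B=199,
                     subset_sizes=(20, 45, 90, 192), component_grid=(1, 2, 3))
report = run_pipeline(cfg, "out")
```

The run prints/writes (seed 1):

```
n_samples_initial     183      # 61 individuals x 3 injections
n_outliers_removed     14      # distinctive cloud on the OD axis
n_samples_retained    169
n_male                 83      # 39 C + 44 SCH
n_female               86      # 45 C + 41 SCH
f_ratio_selected       66      # features with gender F-ratio > F(0.95; 1, n-2) in controls
male_permutation_p    0.005    # = 1/(B+1) at B = 199: no permutation matched the observed accuracy
male_validated_size    45      # smallest VIP-prefix within 1 SE of the best RMSECV
```

and a per-fold metrics table in the layout used for such studies
(`out/model_metrics_male.csv`):

```
fold  n_comp  RMSECV  RMSEP   R2cv    R2p  vip_selected  cal_accuracy  pred_accuracy
   1       2  0.1952 0.1115 0.8472 0.9495            49           1.0            1.0
   2       1  0.1841 0.1230 0.8636 0.9395            52           1.0            1.0
   3       2  0.1800 0.1553 0.8699 0.9031            45           1.0            1.0
   4       2  0.1815 0.1769 0.8680 0.8728            47           1.0            1.0
   5       3  0.1793 0.1644 0.8707 0.8919            48           1.0            1.0
```

RMSECV ≈ 0.18 with R²cv ≈ 0.87 on a 0/1 class code means the
cross-validated predictions sit tightly around their class targets;
45–52 of 192 features carry VIP > 1, i.e. an above-average share of the
discrimination. Synthetic feature m/z values are drawn uniformly, so few
land within 10 ppm of a real lipid — annotate measured tables, or the
bundled library itself, for meaningful assignments:

```python
from lipidchemo.annotation import annotate_feature
annotate_feature(227.2027, "negative", 10.0)[0]
# AnnotationHit(species='FA 14:0', adduct='[M-H]-', formula='C14H28O2',
#               theoretical_mz=227.2016..., ppm=4.6...)
```

The same stages are available from the shell:

```sh
lipidchemo generate --seed 1 --out-dir cohort/
lipidchemo outliers --in-dir cohort/ --out-dir screen/
lipidchemo rank --in-dir cohort/ --out ranking.csv -B 1000
lipidchemo run --seed 1 --out-dir out/
```

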