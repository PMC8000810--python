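# petomics

Radiomic characterization of breast lesions from paired [18F]FDG-PET/CT:
IBSI-style texture features, fold-internal data preparation, and
majority-vote random-forest ensembles under Monte Carlo cross-validation —
with a synthetic lesion-phantom cohort generator so the entire analysis is
reproducible end to end without patient data.

## The problem

Breast cancer cohorts are heavily imbalanced: most referred patients have
malignant tumors, and clinically critical subtypes (triple negative) are a
small minority. Machine-learning models trained naively on such cohorts
learn the majority class and miss exactly the patients who matter. This
package implements an analysis pipeline that measures — and corrects — that
failure mode:

1. **Holomic features.** Each lesion is summarized by 121 features: 5
   conventional SUV metrics (SUVmean, SUVmax, SUVmin, SUVpeak, TLG), 48 PET
   texture features, 50 CT texture features, 14 PET/CT fusion features, and
   4 demographics (age, height, weight, BMI). Texture families are the
   intensity histogram, the merged 3D gray-level co-occurrence matrix
   (GLCM, 13 directions, distance 1), the neighborhood gray-tone difference
   matrix (NGTDM, 26-neighborhood), the gray-level size-zone matrix (GLSZM,
   26-connected zones), and a cross-modality PET×CT co-occurrence matrix.
2. **Data preparation inside each fold.** Redundant features
   (|Pearson r| > 0.95) are removed once, label-free, before validation.
   Inside every fold the training rows then pass through an ordered chain:
   robust-z outlier removal → Tomek-link borderline removal → top-15
   univariate R² feature selection → SMOTE oversampling to class balance.
3. **Ensemble + Monte Carlo validation.** Five differently configured
   random forests vote; performance is aggregated over 100 random
   stratified 90/10 patient-level splits (SENS, SPEC, PPV, NPV, ACC, AUC).
4. **Controls.** A sham analysis (labels permuted per fold) verifies the
   pipeline sits at chance without signal, and an SUVmax-only model
   provides the conventional baseline.

The core statistic is the fold-mean Mann–Whitney AUC,
`P(s⁺ > s⁻) + ½ P(s⁺ = s⁻)`, computed on the ensemble's positive-vote
fraction.

## Worked example

```python
from petomics import (CohortConfig, PreprocessPlan, extract_cohort,
                      generate_cohort, monte_carlo_cv, redundancy_reduce,
                      sham_analysis)

cohort = generate_cohort(CohortConfig(n_patients=40, seed=3))
table = extract_cohort(cohort)              # 41 lesions x 121 features
reduced = redundancy_reduce(table)          # drops |r| > 0.95 columns

report = monte_carlo_cv(reduced, "malignancy", PreprocessPlan(),
                        n_folds=10, seed=1)
print(report.aggregate())
sham = sham_analysis(reduced, "malignancy", PreprocessPlan(),
                     n_folds=10, seed=1)
print(round(sham.aggregate()["AUC"], 3))
```

prints

```
{'SENS': 100.0, 'SPEC': 70.0, 'PPV': 92.5, 'NPV': 100.0, 'ACC': 92.5, 'AUC': 0.85}
0.383
```

i.e. on this small strong-signal cohort the malignancy model detects every
malignant validation lesion (SENS 100%), accepts some false positives
(SPEC 70%), and reaches mean fold AUC 0.85 — while the identical pipeline
run on permuted labels collapses to chance-level AUC. `report.occurrences()`
lists how often each feature entered the fold-wise top-15 selection.

The full study replica (all seven label models, with and without
preparation, plus sham and SUV baselines) runs from the command line:

```bash
petomics run --out study_out --folds 100 --seed 11
```

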