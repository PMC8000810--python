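# Methods

## Scope and model

`petomics` re-creates, as a tested pipeline, a PET/CT radiomics analysis of
breast lesions whose goal is to quantify the effect of training-data
preparation on classifier performance in imbalanced cohorts. The unit of
analysis is a lesion; the unit of cross-validation is a patient. Seven
binary targets are modeled (malignancy, ER, PR, HER2, Ki-67, triple
negative, luminal A/B), each dropping its NA-labeled rows independently.

## Synthetic cohort generator

No public cohort of this kind exists, so the package ships a first-class
generator whose defaults define the study conditions:

* 170 patients, three of whom carry two lesions (173 lesions);
* label prevalences: malignancy 78%; among malignant patients ER 67%,
  PR 60%, HER2 17%, Ki-67 56%, TN 10.4% (with 20% NA, emulating
  incompletely subtyped patients), luminal B 85% of luminal cases.
  Benign patients have NA for all receptor/subtype labels, and a TN
  patient's individual receptors are never positive;
* lesion volumes log-uniform on [1.56, 105] cm³ (median ≈ 12.8 cm³),
  ellipsoidal with mild random anisotropy;
* PET grid 3.6 × 3.6 × 5 mm; CT grid 1.2 × 1.2 × 2 mm over the same
  physical extent, resampled to the PET grid (trilinear) before fusion.

Each lesion is an ellipsoidal uptake profile (benign amplitude ≈ 2.2 SUV
against 0.4 SUV background) plus Gaussian-filtered white-noise speckle.
Class effects enter through a single weight `w` (0 benign, 1 malignant,
+0.5 TN, +0.08–0.12 for ER/PR/Ki-67 positivity, 0 for HER2 and luminal —
so those two models should sit near chance): the uptake multiplier is
`1 + (uptake_effect − 1)·w` and the class-dependent speckle has amplitude
∝ `texture_effect·w` with correlation length ∝ 1/`texture_effect`. Setting
both effects to their neutral values (1 and 0) removes all class contrast,
giving a null cohort. Defaults `uptake_effect = 2.0`, `texture_effect =
2.0` place malignant lesions around SUVmax 6–9 versus 2–3 for benign,
which we consider clinically plausible separation for FDG-avid disease.
A configurable fraction of lesions are outliers (intensities ×8) or
borderline cases (`w = 0.5`, midway between class means); defaults 3% and
5% — these are the rows the outlier/Tomek steps exist to handle.
A 3³-voxel cube of mean 2.0 SUV in a corner of every PET volume serves as
the mediastinum-like reference for tumor-to-background normalization.

One master seed fans out to independent substreams (labels/demographics,
geometry, per-lesion texture fields, per-lesion noise), so changing one
effect never reshuffles the others; identical config + seed is
bit-identical. The generator emulates class structure, imbalance,
redundancy, outliers and borderline cases — it does **not** emulate
scanner physics (PSF, reconstruction artifacts, partial volume), anatomy,
or real benign-lesion SUV histograms; a pass on synthetic data shows the
pipeline's statistical machinery is sound, not that the clinical effect
sizes transfer.

## Delineation

Tumor-to-background normalization divides the PET volume by the mean of
the reference VOI. Segmentation is isocount region growth: the lesion-local
maximum is searched within 15 mm of a seed point, and the mask is the
26-connected component above `fraction × local max`. The isocount fraction
defaults to 0.42 (a common clinical choice; the level is configurable
because no single standard exists). Lesions under 1.56 cm³ are excluded.
Features are computed on raw SUV values; TBR normalization serves only as
the delineation reference.

## Feature definitions and numerical conventions

Discretization uses a fixed bin number (default B = 32) over the in-mask
range: `bin(v) = min(B, 1 + ⌊B(v − min)/(max − min)⌋)`. Fixed-bin-number
makes all texture features invariant to positive affine intensity
rescaling, which the tests assert.

* GLCM: one merged symmetric matrix over the 13 unique distance-1
  directions; 22 standard statistics.
* NGTDM: 26-neighborhood, in-mask neighbors only; coarseness, contrast,
  busyness, complexity, strength.
* GLSZM: 26-connected same-bin zones; 14 standard statistics.
* Fusion: the joint (PET bin, CT bin) distribution of co-located in-mask
  voxels, with 14 GLCM-style statistics. The CT feature list is the PET
  list plus raw HU minimum/maximum (48 + 2 = 50); the group cardinalities
  5/48/50/14/4 = 121 are an enforced contract.
* SUVpeak uses a 1 cm³ sphere (EANM convention), clipped at the volume
  boundary; TLG = SUVmean × volume.

Degenerate inputs return limit values, never NaN: a constant lesion maps
to bin 1 with a degeneracy flag; a single-cell co-occurrence matrix gives
energy 1, contrast 0, correlation 1, information correlations 0; NGTDM
coarseness is capped at 10⁶ when its normalizer vanishes; a single-voxel
mask yields all-zero NGTDM. Entropies are base-2 with 0·log 0 = 0.
Every texture family is verified against literal brute-force enumeration
oracles (pair counting, flood fill, per-voxel neighborhood averaging) on
random phantoms at 1e-10 relative tolerance.

## Preprocessing chain

Redundancy reduction (greedy drop of features with |Pearson r| > 0.95
against an earlier retained feature) is label-free and applied once to the
whole table before cross-validation. The fold-internal steps run in the
fixed order **outlier → borderline → select → balance**:

* outlier: per-feature robust z = (x − median)/(1.4826·MAD); a row is
  removed when |z| > 4 for ≥ 10% of usable features;
* borderline: Tomek links over standardized features; only the
  majority-class member of a link is removed;
* select: top 15 features by squared Pearson correlation with the 0/1
  label (univariate R²), ties broken by column order;
* balance: SMOTE to exact class equality, synthetic rows marked so audits
  can prove they never reach validation.

Where the analysis family was specified only by citation, these are the
canonical representatives of each family (robust-z voting, Tomek links,
SMOTE); each sits behind a small estimator interface and is replaceable.
Selection precedes balancing so synthetic samples are generated in the
selected subspace. All statistics come from fold-training rows only.

## Ensemble and validation

The classifier is five `RandomForestClassifier`s with distinct
configurations (trees ∈ {100, 200}, depth ∈ {∞, 8}, features-per-split
∈ {√p, 0.3p}, leaf ∈ {1, 2}) and distinct derived seeds, deciding by
majority vote; the ROC score is the positive-vote fraction (five discrete
levels — faithful to hard voting; averaging member probabilities is
available as an option). Validation is 100-fold Monte Carlo with
stratified 90/10 splits grouped by patient: stratification guarantees both
classes in every validation set at 10% minority prevalence, grouping keeps
twin lesions on one side. Splits depend only on (seed, fold), so
with/without-preparation comparisons are paired. Per-fold metrics with
zero denominators are excluded from cross-fold means, not imputed. The
sham control permutes patient-level labels once per fold before splitting
(per-fold permutation was chosen over one global permutation: it averages
over permutation draws rather than conditioning on one). AUC is the mean
of fold AUCs (pooling all validation scores is available via config).
Feature importance is the count of folds (0–100) in which a feature
entered the selected top-15; counts always sum to folds × 15.

## Conventional baseline

One-way ANOVA (scipy `f_oneway`) compares each SUV metric between label
groups at p < 0.05, with no multiple-testing correction — each metric is
reported at the plain threshold. SUV-only models reuse the identical
validation machinery restricted to SUVmax (or all five SUV metrics), with
the selection step skipped.

## Problem sizes in the shipped tests

The default test run exercises: oracle equivalence on 100 random ≤ 8³
phantoms; the sham band on the full 170-patient cohort at 100 folds; and
the preparation-benefit comparison on a 10%-minority, moderate-effect
cohort (uptake 1.6, texture 1.5) at 10 seeded replicates × 40 paired folds
per condition — 40 folds is the smallest size at which the fold-mean AUC is
stable enough to resolve the ≈ +0.02 AUC gain the plan delivers there,
while keeping a single-CPU run short. Unit tests
use 12–60-patient cohorts.

## Known limitations

* The texture feature set covers the histogram/GLCM/NGTDM/GLSZM/fusion
  families; shape/morphology and filtered-image features are out of scope,
  and the implementation has not been run against the IBSI digital
  phantom (which requires an external download).
* Tomek-link and SMOTE neighbor searches are O(n²) — appropriate for
  hundreds of lesions, not tens of thousands.
* The generator's CT class effect is deliberately mild and independent;
  it is a device for producing plausible fusion features, not a model of
  breast CT contrast.
* Semi-automatic delineation is modeled as seed + region growth only; no
  manual-edit pathway or multi-observer variability.
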