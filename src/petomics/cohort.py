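"""Synthetic PET/CT breast-lesion cohort generator.

Emulates the statistical structure of a single-center FDG-PET/CT breast
cohort: ~170 patients with 1–2 lesions each, heavily imbalanced binary
labels (malignancy, receptor status, molecular subtype), class-dependent
lesion uptake (malignant and triple-negative lesions are hotter) and
class-dependent spatial heterogeneity, plus controlled fractions of outlier
and borderline lesions that the fold-internal preprocessing is meant to
handle.

Each lesion is an ellipsoidal uptake profile embedded in low-uptake
background on a PET grid with clinical voxel spacing, with additive Gaussian
random-field speckle whose amplitude and correlation length depend on class
(the texture signal), plus iid voxel noise. The paired CT volume lives on a
finer grid with an independent, milder class effect. A cubic mediastinum-like
reference region of known mean is embedded in every PET volume for
tumor-to-background normalization.

One global seed fans out into independent substreams (labels, geometry,
texture fields, noise) so that changing one effect does not reshuffle the
others.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .volumes import BoxRegion, ImageVolume, LesionMask, save_nifti

LABEL_NAMES = ["malignancy", "er", "pr", "her2", "ki67", "tn", "luminal_ab"]

#: positive fraction among non-NA rows, and NA fraction, per label
DEFAULT_PREVALENCE: dict[str, tuple[float, float]] = {
    "malignancy": (0.78, 0.0),
    "er": (0.67, 0.05),
    "pr": (0.60, 0.05),
    "her2": (0.17, 0.05),
    "ki67": (0.56, 0.05),
    "tn": (0.104, 0.20),
    "luminal_ab": (0.85, 0.28),
}

_BACKGROUND_SUV = 0.4
_MEDIASTINUM_SUV = 2.0
_BASE_LESION_SUV = 2.2
_CT_BACKGROUND_HU = -50.0
_CT_BASE_LESION_HU = 40.0


@dataclass
class CohortConfig:
    """Conditions of the simulated study.

    ``uptake_effect`` is the multiplicative SUV shift of malignant vs benign
    lesions; ``texture_effect`` scales the amplitude and spatial frequency of
    the class-dependent heterogeneity field (0 = no texture contrast between
    classes). Defaults mirror the clinical cohort the package emulates:
    170 patients, 78% malignant, TN prevalence ~10% among subtyped patients,
    PET voxels 3.6x3.6x5 mm, CT slices 2 mm, lesion volumes log-uniform on
    [1.56, 105] cm3 (median ~12.8 cm3).
    """

    n_patients: int = 170
    prevalence_map: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_PREVALENCE)
    )
    uptake_effect: float = 2.0
    texture_effect: float = 2.0
    noise_sd: float = 0.15
    outlier_fraction: float = 0.03
    borderline_fraction: float = 0.05
    lesion_volume_range: tuple[float, float] = (1.56, 105.0)
    pet_spacing: tuple[float, float, float] = (3.6, 3.6, 5.0)
    ct_spacing: tuple[float, float, float] = (1.2, 1.2, 2.0)
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients < 10:
            raise ValueError("need at least 10 patients to form 90/10 folds")
        for name, (pos, na) in self.prevalence_map.items():
            if not (0 <= pos <= 1 and 0 <= na <= 1):
                raise ValueError(f"prevalence fractions for {name} must lie in [0, 1]")
        if self.prevalence_map["tn"][0] > self.prevalence_map["malignancy"][0]:
            raise ValueError("TN prevalence cannot exceed malignancy prevalence")
        for frac in (self.outlier_fraction, self.borderline_fraction):
            if not 0 <= frac <= 1:
                raise ValueError("fractions must lie in [0, 1]")
        if self.lesion_volume_range[0] < 1.56:
            raise ValueError("minimum lesion volume must be >= 1.56 cm3")
        n_pos = round(self.prevalence_map["malignancy"][0] * self.n_patients)
        if n_pos < 2 or self.n_patients - n_pos < 2:
            raise ValueError("prevalence yields fewer than 2 patients in a class")


@dataclass
class PatientRecord:
    patient_id: str
    age: float
    height: float
    weight: float
    labels: dict[str, float]  # 1.0 / 0.0 / NaN

    @property
    def bmi(self) -> float:
        return self.weight / (self.height / 100.0) ** 2


@dataclass
class Lesion:
    lesion_id: str
    patient_id: str
    pet: ImageVolume
    ct: ImageVolume
    mask: LesionMask
    reference_voi: BoxRegion
    seed_voxel: tuple[int, int, int]
    is_outlier: bool = False
    is_borderline: bool = False


@dataclass
class Cohort:
    config: CohortConfig
    records: list[PatientRecord]
    lesions: list[Lesion]

    @property
    def records_by_id(self) -> dict[str, PatientRecord]:
        return {r.patient_id: r for r in self.records}

    def label_vector(self, name: str) -> np.ndarray:
        by_id = self.records_by_id
        return np.array([by_id[l.patient_id].labels[name] for l in self.lesions])


def _exact_assignment(rng: np.random.Generator, eligible: np.ndarray, frac: float) -> np.ndarray:
    """Boolean assignment with the exact rounded count of positives."""
    n = eligible.sum()
    k = int(round(frac * n))
    flags = np.zeros(len(eligible), dtype=bool)
    idx = np.flatnonzero(eligible)
    flags[rng.permutation(idx)[:k]] = True
    return flags


def _assign_labels(cfg: CohortConfig, rng: np.random.Generator) -> list[dict[str, float]]:
    n = cfg.n_patients
    pm = cfg.prevalence_map
    malignant = _exact_assignment(rng, np.ones(n, dtype=bool), pm["malignancy"][0])

    labels = [dict.fromkeys(LABEL_NAMES, np.nan) for _ in range(n)]
    for i in range(n):
        labels[i]["malignancy"] = float(malignant[i])

    # receptor/subtype labels exist only for malignant patients; triple
    # negativity forces ER- / PR- / HER2- and removes the luminal subtype
    tn = _exact_assignment(rng, malignant, pm["tn"][0])
    er = _exact_assignment(rng, malignant & ~tn, pm["er"][0])
    pr = _exact_assignment(rng, malignant & ~tn, pm["pr"][0])
    her2 = _exact_assignment(rng, malignant & ~tn, pm["her2"][0])
    ki67 = _exact_assignment(rng, malignant, pm["ki67"][0])
    lum = _exact_assignment(rng, malignant & ~tn, pm["luminal_ab"][0])
    for i in np.flatnonzero(malignant):
        labels[i]["tn"] = float(tn[i])
        labels[i]["er"] = 0.0 if tn[i] else float(er[i])
        labels[i]["pr"] = 0.0 if tn[i] else float(pr[i])
        labels[i]["her2"] = 0.0 if tn[i] else float(her2[i])
        labels[i]["ki67"] = float(ki67[i])
        labels[i]["luminal_ab"] = np.nan if tn[i] else float(lum[i])

    # NA masking applied after assignment
    for name in LABEL_NAMES[1:]:
        na_frac = pm[name][1]
        if na_frac > 0:
            assigned = np.array([not np.isnan(labels[i][name]) for i in range(n)])
            mask_na = _exact_assignment(rng, assigned, na_frac)
            for i in np.flatnonzero(mask_na):
                labels[i][name] = np.nan
    return labels


def _smooth_field(shape, sigma_vox, rng) -> np.ndarray:
    """Unit-variance Gaussian random field (Gaussian-filtered white noise)."""
    noise = rng.standard_normal(shape)
    f = ndimage.gaussian_filter(noise, sigma=sigma_vox)
    sd = f.std()
    return f / sd if sd > 0 else f


def _lesion_effects(labels: dict[str, float], cfg: CohortConfig,
                    borderline: bool) -> tuple[float, float]:
    """Uptake multiplier and texture strength for one lesion.

    Malignancy carries the main effect; triple negativity adds to it;
    ER/PR/Ki-67 add mild shifts (their models should be weakly predictive);
    HER2 and luminal A/B carry no effect (their models should sit at chance).
    Borderline lesions sit midway between the class means.
    """
    def pos(name):
        v = labels[name]
        return (not np.isnan(v)) and v > 0

    w = 0.0
    if borderline:
        w = 0.5
    elif pos("malignancy"):
        w = 1.0
        if pos("tn"):
            w += 0.5
        if pos("er"):
            w += 0.12
        if pos("pr"):
            w += 0.08
        if pos("ki67"):
            w += 0.10
    uptake_mult = 1.0 + (cfg.uptake_effect - 1.0) * w
    texture_strength = cfg.texture_effect * w
    return uptake_mult, texture_strength


def _build_lesion_images(
    cfg: CohortConfig,
    volume_cm3: float,
    uptake_mult: float,
    texture_strength: float,
    is_outlier: bool,
    rng_field: np.random.Generator,
    rng_noise: np.random.Generator,
):
    sp = cfg.pet_spacing
    r_eq_mm = (3.0 * volume_cm3 * 1000.0 / (4.0 * np.pi)) ** (1.0 / 3.0)
    aniso = rng_field.uniform(0.75, 1.3, size=3)
    aniso /= np.prod(aniso) ** (1.0 / 3.0)
    semi_mm = r_eq_mm * aniso

    margin = 5
    shape = tuple(int(np.ceil(2 * semi_mm[a] / sp[a])) + 2 * margin + 1 for a in range(3))
    center = np.array([(s - 1) / 2.0 for s in shape])
    idx = np.indices(shape, dtype=np.float64)
    rho2 = sum(((idx[a] - center[a]) * sp[a] / semi_mm[a]) ** 2 for a in range(3))
    inside = rho2 <= 1.0

    amp = _BASE_LESION_SUV * uptake_mult
    profile = amp * np.clip(1.0 - 0.3 * rho2, 0.0, None) * inside

    # baseline speckle everyone gets, plus the class-dependent component
    base_field = _smooth_field(shape, sigma_vox=2.0, rng=rng_field)
    pet_vals = _BACKGROUND_SUV + profile + inside * 0.10 * amp * base_field
    if texture_strength > 0:
        sigma = 2.0 / max(texture_strength, 0.5)
        cls_field = _smooth_field(shape, sigma_vox=sigma, rng=rng_field)
        pet_vals += inside * 0.15 * amp * min(texture_strength, 4.0) * cls_field
    else:
        rng_field.standard_normal(shape)  # keep the stream aligned across classes
    pet_vals += cfg.noise_sd * rng_noise.standard_normal(shape)

    # mediastinum-like reference cube in a corner, away from the lesion
    voi = BoxRegion((1, 1, 1), (4, 4, 4))
    pet_vals[voi.slices()] = _MEDIASTINUM_SUV + 0.05 * rng_noise.standard_normal((3, 3, 3))
    if is_outlier:
        pet_vals = np.where(inside, pet_vals * 8.0, pet_vals)
    pet_vals = np.clip(pet_vals, 0.0, None)
    pet = ImageVolume(pet_vals, sp, modality="PET")

    # CT on a finer grid over the same physical extent, milder class effect
    extent = np.array(shape) * np.array(sp)
    ct_shape = tuple(int(np.ceil(extent[a] / cfg.ct_spacing[a])) for a in range(3))
    ct_idx = np.indices(ct_shape, dtype=np.float64)
    ct_rho2 = sum(
        ((ct_idx[a] * cfg.ct_spacing[a] - center[a] * sp[a]) / semi_mm[a]) ** 2
        for a in range(3)
    )
    ct_inside = ct_rho2 <= 1.0
    ct_amp = _CT_BASE_LESION_HU * (1.0 + 0.25 * (uptake_mult - 1.0))
    ct_vals = _CT_BACKGROUND_HU + (ct_amp - _CT_BACKGROUND_HU) * ct_inside * np.clip(
        1.0 - 0.2 * ct_rho2, 0.0, None
    )
    ct_tex = 1.0 + 0.3 * texture_strength
    ct_vals += ct_inside * 6.0 * ct_tex * _smooth_field(ct_shape, 3.0, rng_field)
    ct_vals += 4.0 * rng_noise.standard_normal(ct_shape)
    ct = ImageVolume(ct_vals, cfg.ct_spacing, modality="CT")

    mask = LesionMask(inside, sp)
    seed_voxel = tuple(int(round(c)) for c in center)
    return pet, ct, mask, voi, seed_voxel


def generate_cohort(config: CohortConfig) -> Cohort:
    """Generate a reproducible synthetic cohort (same config + seed ->
    bit-identical volumes and labels)."""
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    rng_labels, rng_geom = (np.random.default_rng(s) for s in ss.spawn(2))

    labels = _assign_labels(config, rng_labels)
    n = config.n_patients
    ages = np.clip(rng_labels.normal(57, 12, n), 25, 90)
    heights = np.clip(rng_labels.normal(165, 7, n), 145, 190)
    weights = np.clip(rng_labels.normal(70, 13, n), 42, 130)
    records = [
        PatientRecord(f"P{i:04d}", float(ages[i]), float(heights[i]), float(weights[i]), labels[i])
        for i in range(n)
    ]

    # a few patients carry two lesions (3 of 170 in the emulated cohort)
    n_two = int(round(3.0 / 170.0 * n))
    two_lesion = set(rng_geom.permutation(n)[:n_two])
    lesion_owner = [i for i in range(n) for _ in range(2 if i in two_lesion else 1)]

    n_lesions = len(lesion_owner)
    lo, hi = config.lesion_volume_range
    volumes = np.exp(rng_geom.uniform(np.log(lo), np.log(hi), n_lesions))
    outlier = _exact_assignment(rng_geom, np.ones(n_lesions, bool), config.outlier_fraction)
    borderline = _exact_assignment(rng_geom, ~outlier, config.borderline_fraction)

    field_streams = np.random.SeedSequence((config.seed, 1)).spawn(n_lesions)
    noise_streams = np.random.SeedSequence((config.seed, 2)).spawn(n_lesions)

    lesions = []
    for k, owner in enumerate(lesion_owner):
        u, t = _lesion_effects(labels[owner], config, bool(borderline[k]))
        pet, ct, mask, voi, seed_voxel = _build_lesion_images(
            config, float(volumes[k]), u, t, bool(outlier[k]),
            np.random.default_rng(field_streams[k]),
            np.random.default_rng(noise_streams[k]),
        )
        lesions.append(
            Lesion(f"L{k:04d}", records[owner].patient_id, pet, ct, mask, voi,
                   seed_voxel, bool(outlier[k]), bool(borderline[k]))
        )
    return Cohort(config, records, lesions)


def cohort_to_disk(cohort: Cohort, directory: str) -> dict:
    """Write the cohort as NIfTI volumes + records CSV + JSON manifest."""
    os.makedirs(directory, exist_ok=True)
    entries = []
    for lesion in cohort.lesions:
        paths = {
            "pet": os.path.join(directory, f"{lesion.lesion_id}_pet.nii.gz"),
            "ct": os.path.join(directory, f"{lesion.lesion_id}_ct.nii.gz"),
            "mask": os.path.join(directory, f"{lesion.lesion_id}_mask.nii.gz"),
        }
        try:
            save_nifti(lesion.pet, paths["pet"])
            save_nifti(lesion.ct, paths["ct"])
            save_nifti(lesion.mask, paths["mask"])
        except OSError as exc:
            raise OSError(f"failed writing lesion files under {directory}: {exc}") from exc
        entries.append({"lesion_id": lesion.lesion_id, "patient_id": lesion.patient_id, **paths})

    rows = []
    for r in cohort.records:
        rows.append({"patient_id": r.patient_id, "age": r.age, "height": r.height,
                     "weight": r.weight, "bmi": r.bmi, **r.labels})
    records_path = os.path.join(directory, "records.csv")
    pd.DataFrame(rows).to_csv(records_path, index=False)

    cfg = cohort.config
    manifest = {
        "config": {
            "n_patients": cfg.n_patients,
            "uptake_effect": cfg.uptake_effect,
            "texture_effect": cfg.texture_effect,
            "noise_sd": cfg.noise_sd,
            "outlier_fraction": cfg.outlier_fraction,
            "borderline_fraction": cfg.borderline_fraction,
            "lesion_volume_range": list(cfg.lesion_volume_range),
            "pet_spacing": list(cfg.pet_spacing),
            "ct_spacing": list(cfg.ct_spacing),
            "seed": cfg.seed,
        },
        "records": records_path,
        "lesions": entries,
    }
    manifest_path = os.path.join(directory, "manifest.json")
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


def manifest_content_hash(directory: str) -> str:
    """SHA-256 over the records CSV and all volume files, for reproducibility
    audits of regenerated cohorts."""
    manifest = json.load(open(os.path.join(directory, "manifest.json")))
    h = hashlib.sha256()
    files = [manifest["records"]]
    for e in manifest["lesions"]:
        files += [e["pet"], e["ct"], e["mask"]]
    import gzip
    for path in files:
        opener = gzip.open if path.endswith(".gz") else open
        with opener(path, "rb") as fh:
            h.update(fh.read())
    return h.hexdigest()
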