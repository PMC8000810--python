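"""Per-lesion holomic feature extraction and the lesion-by-feature table."""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .manifest import (
    GROUP_CARDINALITIES,
    GROUPS,
    default_manifest,
    feature_groups,
    validate_manifest,
)
from .suv import suv_metrics
from .texture import (
    discretize,
    fusion_features,
    glcm_features,
    glszm_features,
    histogram_features,
    ngtdm_features,
)
from .volumes import ImageVolume, LesionMask, resample_to_grid

LABEL_NAMES = ["malignancy", "er", "pr", "her2", "ki67", "tn", "luminal_ab"]

_LABEL_PREFIX = "label__"
_META_COLUMNS = ["patient_id"]


@dataclass
class FeatureTable:
    """Lesions × named features, plus tri-state labels and patient grouping.

    ``features`` is numeric (lesion_id index); ``labels`` holds 1.0 / 0.0 /
    NaN per target; ``patient_ids`` ties twin lesions of one patient together
    for grouped cross-validation splits.
    """

    features: pd.DataFrame
    labels: pd.DataFrame
    patient_ids: pd.Series
    groups: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.features.index.equals(self.labels.index):
            raise ValueError("features and labels must share the lesion index")

    @property
    def n_lesions(self) -> int:
        return len(self.features)

    def rows_with_label(self, label_name: str) -> "FeatureTable":
        """Drop lesions whose label is NA for the given target."""
        keep = self.labels[label_name].notna()
        return FeatureTable(
            self.features.loc[keep],
            self.labels.loc[keep],
            self.patient_ids.loc[keep],
            self.groups,
        )

    def to_csv(self, path: str) -> None:
        df = self.features.copy()
        df["patient_id"] = self.patient_ids
        for name in self.labels.columns:
            df[_LABEL_PREFIX + name] = self.labels[name]
        df.to_csv(path, index_label="lesion_id")

    @classmethod
    def from_csv(cls, path: str, groups: dict[str, str] | None = None) -> "FeatureTable":
        df = pd.read_csv(path, index_col="lesion_id")
        label_cols = [c for c in df.columns if c.startswith(_LABEL_PREFIX)]
        labels = df[label_cols].rename(columns=lambda c: c[len(_LABEL_PREFIX):])
        feats = df.drop(columns=label_cols + _META_COLUMNS)
        return cls(feats, labels, df["patient_id"], groups or feature_groups())


def texture_features(volume: ImageVolume, mask: LesionMask, n_bins: int = 32) -> dict[str, float]:
    """All single-modality texture features (histogram + GLCM + NGTDM + GLSZM)."""
    d = discretize(volume, mask, n_bins)
    raw = volume.values[mask.voxels]
    out: dict[str, float] = {}
    out.update(histogram_features(d, raw_in_mask=raw))
    out.update(glcm_features(d))
    out.update(ngtdm_features(d))
    out.update(glszm_features(d))
    return out


def extract_all(
    pet: ImageVolume,
    ct: ImageVolume,
    mask: LesionMask,
    record,
    manifest: dict[str, list[str]] | None = None,
    n_bins: int = 32,
) -> dict[str, float]:
    """The 121-entry holomic feature vector of one lesion.

    CT is resampled to the PET grid (trilinear) when the grids differ; the
    fusion matrix couples co-located PET and CT bins. Raises if any produced
    value is non-finite or if the manifest breaks the 5/48/50/14/4 contract.
    """
    manifest = manifest or default_manifest()
    validate_manifest(manifest)

    if ct.shape != pet.shape or ct.spacing != pet.spacing:
        ct = resample_to_grid(ct, pet)

    values: dict[str, float] = {}
    values.update(suv_metrics(pet, mask))

    pet_tex = texture_features(pet, mask, n_bins)
    values.update({f"pet_{k}": v for k, v in pet_tex.items()})

    ct_tex = texture_features(ct, mask, n_bins)
    values.update({f"ct_{k}": v for k, v in ct_tex.items()})
    hu = ct.values[mask.voxels]
    values["ct_hu_min"] = float(hu.min())
    values["ct_hu_max"] = float(hu.max())

    pet_d = discretize(pet, mask, n_bins)
    ct_d = discretize(ct, mask, n_bins)
    values.update(fusion_features(pet_d, ct_d))

    values.update(
        {"age": float(record.age), "height": float(record.height),
         "weight": float(record.weight), "bmi": float(record.bmi)}
    )

    ordered = {name: values[name] for group in GROUPS for name in manifest[group]}
    if len(ordered) != sum(GROUP_CARDINALITIES.values()):
        raise ValueError(f"feature vector has {len(ordered)} entries, expected 121")
    for name, v in ordered.items():
        if not np.isfinite(v):
            raise ValueError(f"non-finite value for feature {name!r}: {v}")
    return ordered


def extract_cohort(cohort, manifest=None, n_bins: int = 32) -> FeatureTable:
    """Feature table for a generated synthetic cohort (see petomics.cohort)."""
    manifest = manifest or default_manifest()
    rows, labels, pids, index = [], [], [], []
    for lesion in cohort.lesions:
        record = cohort.records_by_id[lesion.patient_id]
        rows.append(extract_all(lesion.pet, lesion.ct, lesion.mask, record, manifest, n_bins))
        labels.append({k: _tristate(v) for k, v in record.labels.items()})
        pids.append(lesion.patient_id)
        index.append(lesion.lesion_id)
    features = pd.DataFrame(rows, index=pd.Index(index, name="lesion_id"))
    label_df = pd.DataFrame(labels, index=features.index, columns=LABEL_NAMES, dtype=float)
    return FeatureTable(features, label_df, pd.Series(pids, index=features.index, name="patient_id"),
                        feature_groups(manifest))


def _tristate(v) -> float:
    if v is None or (isinstance(v, float) and np.isnan(v)):
        return np.nan
    return float(bool(v))


def save_extraction_sidecar(path: str, n_bins: int, manifest) -> None:
    with open(path, "w") as fh:
        json.dump({"n_bins": n_bins, "groups": {g: len(v) for g, v in manifest.items()}}, fh, indent=2)
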