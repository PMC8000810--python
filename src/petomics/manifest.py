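"""The holomic feature manifest: which features make up the 121-entry vector.

The vector is 5 SUV metrics + 48 PET texture features + 50 CT texture
features (the PET list plus raw HU minimum/maximum) + 14 PET/CT fusion
features + 4 demographics. The manifest is configuration — lists can be
swapped via YAML — but the 5/48/50/14/4 group cardinalities are an enforced
contract of ``extract_all``.
"""

from __future__ import annotations

import yaml

from .suv import SUV_METRICS
from .texture import FUSION_FEATURES, GLCM_FEATURES, GLSZM_FEATURES

GROUPS = ("SUV", "PET", "CT", "FUSION", "DEMOGRAPHIC")
GROUP_CARDINALITIES = {"SUV": 5, "PET": 48, "CT": 50, "FUSION": 14, "DEMOGRAPHIC": 4}

_HIST = ["hist_mean", "hist_variance", "hist_skewness", "hist_kurtosis",
         "hist_uniformity", "hist_entropy", "intensity_range"]
_NGTDM = ["ngtdm_coarseness", "ngtdm_contrast", "ngtdm_busyness",
          "ngtdm_complexity", "ngtdm_strength"]

#: 7 histogram + 22 GLCM + 5 NGTDM + 14 GLSZM = 48 texture features
TEXTURE_BASE = _HIST + [f"glcm_{k}" for k in GLCM_FEATURES] + _NGTDM + [
    f"glszm_{k}" for k in GLSZM_FEATURES
]

DEMOGRAPHICS = ["age", "height", "weight", "bmi"]


def default_manifest() -> dict[str, list[str]]:
    """Feature names per group, fully qualified with a modality prefix."""
    return {
        "SUV": list(SUV_METRICS),
        "PET": [f"pet_{name}" for name in TEXTURE_BASE],
        "CT": [f"ct_{name}" for name in TEXTURE_BASE] + ["ct_hu_min", "ct_hu_max"],
        "FUSION": [f"fusion_{k}" for k in FUSION_FEATURES],
        "DEMOGRAPHIC": list(DEMOGRAPHICS),
    }


def validate_manifest(manifest: dict[str, list[str]]) -> None:
    for group, n in GROUP_CARDINALITIES.items():
        got = len(manifest.get(group, []))
        if got != n:
            raise ValueError(f"manifest group {group} has {got} features, expected {n}")
    names = [n for g in GROUPS for n in manifest[g]]
    if len(set(names)) != len(names):
        raise ValueError("manifest contains duplicate feature names")


def feature_groups(manifest: dict[str, list[str]] | None = None) -> dict[str, str]:
    """Map feature name -> group tag."""
    manifest = manifest or default_manifest()
    return {name: group for group in GROUPS for name in manifest[group]}


def load_manifest(path: str) -> dict[str, list[str]]:
    with open(path) as fh:
        manifest = yaml.safe_load(fh)
    validate_manifest(manifest)
    return manifest


def save_manifest(manifest: dict[str, list[str]], path: str) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
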