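import numpy as np
import pytest

from petomics import (
    CohortConfig,
    ImageVolume,
    LesionMask,
    extract_cohort,
    generate_cohort,
    redundancy_reduce,
)

PET_SPACING = (3.6, 3.6, 5.0)


def make_pet(values, spacing=PET_SPACING):
    return ImageVolume(np.asarray(values, dtype=float), spacing, modality="PET")


def make_mask(voxels, spacing=PET_SPACING):
    return LesionMask(np.asarray(voxels, dtype=bool), spacing)


def random_phantom(rng, max_side=8, n_bins=5):
    """Random discretized phantom: bins in 1..n_bins, random nonempty mask."""
    shape = tuple(rng.integers(2, max_side + 1, size=3))
    bins = rng.integers(1, n_bins + 1, size=shape)
    mask = rng.random(shape) < rng.uniform(0.4, 0.9)
    if not mask.any():
        mask.flat[rng.integers(0, mask.size)] = True
    bins = np.where(mask, bins, 0)
    return bins.astype(np.int64), mask, n_bins


@pytest.fixture(scope="session")
def tiny_cohort():
    """12-patient cohort for fast structural tests."""
    return generate_cohort(CohortConfig(n_patients=12, seed=5))


@pytest.fixture(scope="session")
def tiny_table(tiny_cohort):
    return extract_cohort(tiny_cohort)


@pytest.fixture(scope="session")
def study_cohort():
    """Full-scale replica cohort: 170 patients, strong class effects."""
    return generate_cohort(CohortConfig(seed=11))


@pytest.fixture(scope="session")
def study_table(study_cohort):
    return extract_cohort(study_cohort)


@pytest.fixture(scope="session")
def study_reduced(study_table):
    return redundancy_reduce(study_table)


@pytest.fixture(scope="session")
def minority_reduced():
    """10%-minority cohort with moderate effects, for the imbalance study."""
    prevalence = dict(CohortConfig().prevalence_map)
    prevalence["malignancy"] = (0.10, 0.0)
    prevalence["tn"] = (0.08, 0.2)
    cfg = CohortConfig(
        n_patients=170,
        prevalence_map=prevalence,
        uptake_effect=1.6,
        texture_effect=1.5,
        seed=23,
    )
    return redundancy_reduce(extract_cohort(generate_cohort(cfg)))
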