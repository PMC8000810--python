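"""Lesion delineation on PET: TBR normalization, isocount region growing,
and the minimum-volume inclusion filter.

The segmentation is the semi-automatic scheme used in clinical FDG-PET
workstations: a reader drops a seed near the lesion, the algorithm locates
the lesion-local SUV maximum within a small search radius, and the mask is
the connected set of voxels above a fixed fraction of that maximum (an
isocount / isocontour threshold).
"""

from __future__ import annotations

import numpy as np
from skimage import measure

from .volumes import BoxRegion, ImageVolume, LesionMask

#: default isocount level, as a fraction of the lesion-local maximum
DEFAULT_THRESHOLD_FRACTION = 0.42
#: default radius (mm) around the seed searched for the local maximum
DEFAULT_SEARCH_RADIUS_MM = 15.0
#: smallest lesion volume retained for radiomic analysis, cm³
MIN_LESION_VOLUME_CM3 = 1.56


def tbr_normalize(pet: ImageVolume, background_voi: BoxRegion) -> ImageVolume:
    """Divide a PET volume by the mean SUV of a background reference VOI.

    The reference is a cubic volume of interest placed over the mediastinum;
    the result is a tumor-to-background-ratio (TBR) image. The input volume
    is left unmodified.
    """
    background = background_voi.extract(pet)
    if background.size == 0:
        raise ValueError("background VOI is empty")
    mean_bg = float(background.mean())
    if mean_bg <= 0:
        raise ValueError(f"degenerate background reference (mean SUV = {mean_bg})")
    return ImageVolume(pet.values / mean_bg, pet.spacing, pet.origin, pet.modality)


def isocount_segment(
    pet: ImageVolume,
    seed_voxel: tuple[int, int, int],
    threshold_fraction: float = DEFAULT_THRESHOLD_FRACTION,
    search_radius_mm: float = DEFAULT_SEARCH_RADIUS_MM,
) -> LesionMask:
    """Grow a 3D lesion mask from a seed by isocount thresholding.

    The lesion-local maximum is located within ``search_radius_mm`` of the
    seed; the mask is the 26-connected component, containing that maximum, of
    ``{voxel : value >= threshold_fraction * local_max}``.
    """
    if not 0 < threshold_fraction < 1:
        raise ValueError("threshold_fraction must lie strictly in (0, 1)")
    seed = tuple(int(i) for i in seed_voxel)
    if any(i < 0 or i >= n for i, n in zip(seed, pet.shape)):
        raise ValueError(f"seed voxel {seed} lies outside the volume {pet.shape}")

    # physical-distance ball around the seed
    idx = np.indices(pet.shape, dtype=np.float64)
    dist2 = sum(
        ((idx[a] - seed[a]) * pet.spacing[a]) ** 2 for a in range(3)
    )
    ball = dist2 <= search_radius_mm**2
    local_max = float(pet.values[ball].max())
    max_pos = np.unravel_index(
        np.argmax(np.where(ball, pet.values, -np.inf)), pet.shape
    )

    above = pet.values >= threshold_fraction * local_max
    labels = measure.label(above, connectivity=3)
    component = labels == labels[max_pos]
    if not component.any() or labels[max_pos] == 0:
        raise ValueError("isocount threshold produced an empty component")
    return LesionMask(component, pet.spacing)


def volume_filter(mask: LesionMask, min_cm3: float = MIN_LESION_VOLUME_CM3) -> bool:
    """Accept a lesion iff its physical volume reaches ``min_cm3``."""
    return mask.volume_cm3 >= min_cm3
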