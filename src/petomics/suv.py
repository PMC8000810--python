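"""Conventional SUV metrics of a delineated PET lesion.

SUVpeak follows the EANM convention: the highest mean uptake within a 1 cm³
sphere centered at any in-mask voxel (the sphere may extend beyond the mask
but is clipped at the volume boundary). TLG (total lesion glycolysis) is
SUVmean times the metabolic volume in cm³.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .volumes import ImageVolume, LesionMask

SUV_METRICS = ["suv_mean", "suv_max", "suv_min", "suv_peak", "suv_tlg"]

#: radius (mm) of a 1 cm³ sphere
PEAK_SPHERE_RADIUS_MM = (3.0 / (4.0 * np.pi) * 1000.0) ** (1.0 / 3.0)


def _sphere_kernel(spacing: tuple[float, float, float], radius_mm: float) -> np.ndarray:
    half = [max(1, int(np.ceil(radius_mm / s))) for s in spacing]
    grids = np.indices([2 * h + 1 for h in half], dtype=np.float64)
    d2 = sum(((grids[a] - half[a]) * spacing[a]) ** 2 for a in range(3))
    return (d2 <= radius_mm**2).astype(np.float64)


def suv_peak(pet: ImageVolume, mask: LesionMask, radius_mm: float = PEAK_SPHERE_RADIUS_MM) -> float:
    kernel = _sphere_kernel(pet.spacing, radius_mm)
    # edge clipping: divide sum inside volume by the count inside volume
    sums = ndimage.correlate(pet.values, kernel, mode="constant", cval=0.0)
    cnts = ndimage.correlate(np.ones(pet.shape), kernel, mode="constant", cval=0.0)
    means = sums / cnts
    return float(means[mask.voxels].max())


def suv_metrics(pet: ImageVolume, mask: LesionMask) -> dict[str, float]:
    """SUVmean, SUVmax, SUVmin, SUVpeak and TLG over the lesion mask."""
    if mask.voxel_count == 0:
        raise ValueError("empty lesion mask")
    vals = pet.values[mask.voxels]
    mean = float(vals.mean())
    return {
        "suv_mean": mean,
        "suv_max": float(vals.max()),
        "suv_min": float(vals.min()),
        "suv_peak": suv_peak(pet, mask),
        "suv_tlg": mean * mask.volume_cm3,
    }
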