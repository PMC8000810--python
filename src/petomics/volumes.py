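"""3D image containers and grid operations.

PET volumes carry body-weight standardized uptake values (SUV, dimensionless);
CT volumes carry Hounsfield units. Both are plain scalar grids with physical
voxel spacing in millimetres — enough geometry for lesion-level radiomics,
which never needs patient-space orientation matrices.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
from scipy import ndimage


@dataclass
class ImageVolume:
    """A 3D scalar image on a regular grid.

    Parameters
    ----------
    values : ndarray, shape (nx, ny, nz)
        Voxel values (SUV for PET, HU for CT).
    spacing : tuple of 3 floats
        Physical voxel size along each axis, in mm.
    origin : tuple of 3 floats
        Physical coordinate of voxel (0, 0, 0), in mm.
    modality : str
        Free-form tag, conventionally ``"PET"`` or ``"CT"``.
    """

    values: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    modality: str = "PET"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3:
            raise ValueError(f"expected a 3D array, got ndim={self.values.ndim}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"voxel spacing must be positive, got {self.spacing}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("volume contains non-finite values")
        if self.modality.upper() == "PET" and self.values.min() < 0:
            raise ValueError("PET volume contains negative SUV values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_volume_cm3(self) -> float:
        """Volume of one voxel in cm³ (spacing is in mm; 1 cm³ = 1000 mm³)."""
        return float(np.prod(self.spacing)) / 1000.0

    def copy(self) -> "ImageVolume":
        return ImageVolume(self.values.copy(), self.spacing, self.origin, self.modality)


@dataclass
class LesionMask:
    """Binary lesion mask on the PET grid."""

    voxels: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels).astype(bool)
        if self.voxels.ndim != 3:
            raise ValueError("mask must be 3D")
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise ValueError("voxel spacing must be positive")

    @property
    def voxel_count(self) -> int:
        return int(self.voxels.sum())

    @property
    def volume_cm3(self) -> float:
        return self.voxel_count * float(np.prod(self.spacing)) / 1000.0

    def indices(self) -> np.ndarray:
        """(n, 3) integer coordinates of in-mask voxels."""
        return np.argwhere(self.voxels)


@dataclass
class BoxRegion:
    """Axis-aligned voxel box, used for the mediastinum reference VOI."""

    lo: tuple[int, int, int]
    hi: tuple[int, int, int]  # exclusive

    def slices(self) -> tuple[slice, slice, slice]:
        return tuple(slice(l, h) for l, h in zip(self.lo, self.hi))

    def extract(self, volume: ImageVolume) -> np.ndarray:
        return volume.values[self.slices()]


def resample_to_grid(source: ImageVolume, target: ImageVolume) -> ImageVolume:
    """Resample ``source`` onto the grid of ``target`` by trilinear interpolation.

    Used to bring the finer CT grid onto the PET grid before fusion-texture
    computation. Physical coordinates are aligned through each volume's origin
    and spacing; voxels of the target grid falling outside the source extent
    take the nearest-edge value.
    """
    tgt_idx = np.indices(target.shape, dtype=np.float64)
    coords = [
        (tgt_idx[a] * target.spacing[a] + target.origin[a] - source.origin[a])
        / source.spacing[a]
        for a in range(3)
    ]
    values = ndimage.map_coordinates(
        source.values, np.stack(coords), order=1, mode="nearest"
    )
    return ImageVolume(values, target.spacing, target.origin, source.modality)


def save_nifti(volume: ImageVolume | LesionMask, path: str) -> None:
    if isinstance(volume, LesionMask):
        data = volume.voxels.astype(np.uint8)
        spacing = volume.spacing
    else:
        data = volume.values
        spacing = volume.spacing
    affine = np.diag(list(spacing) + [1.0])
    if isinstance(volume, ImageVolume):
        affine[:3, 3] = volume.origin
    nib.save(nib.Nifti1Image(data, affine), path)


def load_nifti(path: str, modality: str = "PET") -> ImageVolume:
    img = nib.load(path)
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    origin = tuple(float(x) for x in img.affine[:3, 3])
    return ImageVolume(np.asarray(img.dataobj, dtype=np.float64), spacing, origin, modality)


def load_nifti_mask(path: str) -> LesionMask:
    img = nib.load(path)
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return LesionMask(np.asarray(img.dataobj) > 0.5, spacing)
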