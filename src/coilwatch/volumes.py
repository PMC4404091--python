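"""Image containers and file I/O.

Each 3DRA session yields two reconstructions on one grid: a *subtracted*
volume showing contrast-filled lumen (vessels, aneurysm sac or residual
blood) and a *baseline* (bone-scan) volume showing skull and the metal coil
mass.  Both are plain scalar grids with physical spacing in millimetres.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal

import numpy as np
import SimpleITK as sitk

Modality = Literal["subtracted", "baseline"]


@dataclass
class ImageVolume:
    """A 3D scalar image with physical geometry.

    Parameters
    ----------
    values : (nx, ny, nz) float array
        Voxel intensities, indexed ``values[i, j, k]``.
    spacing : length-3 sequence, mm
        Voxel edge lengths per axis; isotropic 0.22 mm for 3DRA.
    origin : length-3 sequence, mm
        Physical position of voxel (0, 0, 0).
    modality : {"subtracted", "baseline"}
    """

    values: np.ndarray
    spacing: tuple[float, float, float] = (0.22, 0.22, 0.22)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    modality: Modality = "subtracted"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3:
            raise ValueError(f"expected a 3D array, got rank {self.values.ndim}")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 positive lengths, got {self.spacing}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("image contains non-finite values")
        if self.modality not in ("subtracted", "baseline"):
            raise ValueError(f"unknown modality {self.modality!r}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def with_values(self, values: np.ndarray) -> "ImageVolume":
        return replace(self, values=np.asarray(values, dtype=np.float64))

    def index_to_physical(self, index: np.ndarray) -> np.ndarray:
        """Voxel index (possibly fractional) -> physical point in mm."""
        return np.asarray(self.origin) + np.asarray(index) * np.asarray(self.spacing)

    def physical_to_index(self, point_mm: np.ndarray) -> np.ndarray:
        return (np.asarray(point_mm) - np.asarray(self.origin)) / np.asarray(self.spacing)


@dataclass
class BinaryMask:
    """A boolean voxel mask inheriting grid geometry from its source volume."""

    values: np.ndarray
    spacing: tuple[float, float, float] = (0.22, 0.22, 0.22)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values).astype(bool)
        if self.values.ndim != 3:
            raise ValueError(f"expected a 3D mask, got rank {self.values.ndim}")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def voxel_count(self) -> int:
        return int(self.values.sum())

    def volume_cc(self) -> float:
        """Voxel-count volume in cc (1 cc = 1000 mm^3)."""
        return self.voxel_count() * self.voxel_volume_mm3 / 1000.0

    def is_empty(self) -> bool:
        return not self.values.any()

    def with_values(self, values: np.ndarray) -> "BinaryMask":
        return replace(self, values=np.asarray(values).astype(bool))

    def same_grid(self, other: "BinaryMask | ImageVolume") -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing)
            and np.allclose(self.origin, other.origin)
        )

    def index_to_physical(self, index: np.ndarray) -> np.ndarray:
        return np.asarray(self.origin) + np.asarray(index) * np.asarray(self.spacing)

    def physical_to_index(self, point_mm: np.ndarray) -> np.ndarray:
        return (np.asarray(point_mm) - np.asarray(self.origin)) / np.asarray(self.spacing)


def mask_like(vol: ImageVolume, values: np.ndarray) -> BinaryMask:
    return BinaryMask(values=values, spacing=vol.spacing, origin=vol.origin)


def crop_box(vol: ImageVolume, center_mm, halfwidth_mm: float) -> ImageVolume:
    """Axis-aligned crop around a physical point, origin adjusted.

    The box is clipped to the grid; physical coordinates of retained voxels
    are unchanged.
    """
    lo = np.floor(vol.physical_to_index(np.asarray(center_mm, float) - halfwidth_mm)).astype(int)
    hi = np.ceil(vol.physical_to_index(np.asarray(center_mm, float) + halfwidth_mm)).astype(int) + 1
    lo = np.clip(lo, 0, np.array(vol.shape))
    hi = np.clip(hi, 0, np.array(vol.shape))
    if np.any(hi - lo < 4):
        raise ValueError("crop box does not usefully overlap the grid")
    window = tuple(slice(int(a), int(b)) for a, b in zip(lo, hi))
    return ImageVolume(
        values=vol.values[window],
        spacing=vol.spacing,
        origin=tuple(vol.index_to_physical(lo)),
        modality=vol.modality,
    )


# ---------------------------------------------------------------------------
# File I/O (NIfTI / MetaImage through SimpleITK)
# ---------------------------------------------------------------------------

def write_volume(vol: ImageVolume | BinaryMask, path: str | Path) -> None:
    """Write a volume or mask as .nii/.nii.gz/.mha (format from extension)."""
    arr = vol.values
    if arr.dtype == bool:
        arr = arr.astype(np.uint8)
    # SimpleITK arrays are indexed [z, y, x]
    img = sitk.GetImageFromArray(np.ascontiguousarray(arr.transpose(2, 1, 0)))
    img.SetSpacing(tuple(vol.spacing))
    img.SetOrigin(tuple(vol.origin))
    sitk.WriteImage(img, str(path))


def read_volume(path: str | Path, modality: Modality = "subtracted") -> ImageVolume:
    img = sitk.ReadImage(str(path))
    arr = sitk.GetArrayFromImage(img).transpose(2, 1, 0).astype(np.float64)
    return ImageVolume(
        values=arr,
        spacing=tuple(img.GetSpacing()),
        origin=tuple(img.GetOrigin()),
        modality=modality,
    )


def read_mask(path: str | Path) -> BinaryMask:
    img = sitk.ReadImage(str(path))
    arr = sitk.GetArrayFromImage(img).transpose(2, 1, 0)
    return BinaryMask(values=arr > 0, spacing=tuple(img.GetSpacing()), origin=tuple(img.GetOrigin()))
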