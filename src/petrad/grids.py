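"""Minimal 3D volume container with physical geometry.

A :class:`VolumeGrid` couples a scalar voxel array with its voxel spacing,
origin and a modality tag (CT Hounsfield units, raw PET activity in Bq/mL,
or unitless SUV).  Physical position of voxel index ``i`` (0-based) is
``origin + i * spacing`` (mm, axis-aligned grids only).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = ["Modality", "VolumeGrid", "load_nifti", "save_nifti"]


class Modality:
    CT = "CT"
    PET_ACTIVITY = "PET_ACTIVITY"
    PET_SUV = "PET_SUV"
    MASK = "MASK"

    ALL = (CT, PET_ACTIVITY, PET_SUV, MASK)


@dataclass
class VolumeGrid:
    """One 3D scalar image with voxel spacing (mm), origin (mm) and modality."""

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    modality: str = Modality.PET_SUV

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError(f"expected a 3D array, got ndim={self.voxels.ndim}")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive, got {self.spacing}")
        if self.modality not in Modality.ALL:
            raise ValueError(f"unknown modality {self.modality!r}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape  # type: ignore[return-value]

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def physical_extent(self) -> np.ndarray:
        """(3, 2) array of [min, max] physical coordinates of voxel centers."""
        lo = np.asarray(self.origin, dtype=float)
        hi = lo + (np.asarray(self.shape) - 1) * np.asarray(self.spacing)
        return np.stack([lo, hi], axis=1)

    def index_to_physical(self, idx: np.ndarray) -> np.ndarray:
        return np.asarray(self.origin) + np.asarray(idx, dtype=float) * np.asarray(self.spacing)

    def physical_to_index(self, pos: np.ndarray) -> np.ndarray:
        """Continuous (fractional) voxel index of a physical position."""
        return (np.asarray(pos, dtype=float) - np.asarray(self.origin)) / np.asarray(self.spacing)

    def with_voxels(self, voxels: np.ndarray, modality: str | None = None) -> "VolumeGrid":
        return replace(self, voxels=voxels, modality=modality or self.modality)


def save_nifti(vol: VolumeGrid, path: str | Path) -> None:
    affine = np.diag(list(vol.spacing) + [1.0])
    affine[:3, 3] = vol.origin
    img = nib.Nifti1Image(np.asarray(vol.voxels), affine)
    img.header.set_zooms(vol.spacing)
    nib.save(img, str(path))


def load_nifti(path: str | Path, modality: str = Modality.PET_SUV) -> VolumeGrid:
    img = nib.load(str(path))
    affine = img.affine
    spacing = tuple(float(s) for s in img.header.get_zooms()[:3])
    origin = tuple(float(x) for x in affine[:3, 3])
    data = np.asanyarray(img.dataobj)
    if modality == Modality.MASK:
        data = np.rint(data).astype(np.int32)
    return VolumeGrid(voxels=data, spacing=spacing, origin=origin, modality=modality)
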