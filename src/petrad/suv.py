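"""SUV standardization and isotropic resampling.

PET activity concentration (Bq/mL) is converted to the standardized uptake
value SUV = C * body_weight[g] / decay_corrected_dose[Bq], with the injected
dose decayed over the uptake interval using the 18F half-life (109.77 min).
Both modalities are then resampled to a common 1x1x1 mm^3 grid: intensity
images by trilinear interpolation, label masks by nearest neighbor so labels
stay integral.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import map_coordinates

from .grids import Modality, VolumeGrid

__all__ = ["F18_HALF_LIFE_MIN", "AcquisitionInfo", "to_suv", "resample_isotropic", "map_mask_to_ct"]

F18_HALF_LIFE_MIN = 109.77


@dataclass
class AcquisitionInfo:
    """Injection/weight metadata needed for SUV conversion."""

    injected_dose_bq: float
    body_weight_kg: float
    uptake_interval_min: float = 60.0
    half_life_min: float = F18_HALF_LIFE_MIN

    def __post_init__(self) -> None:
        for name in ("injected_dose_bq", "body_weight_kg", "half_life_min"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.uptake_interval_min < 0:
            raise ValueError("uptake_interval_min must be >= 0")

    @property
    def decay_corrected_dose_bq(self) -> float:
        return self.injected_dose_bq * 2.0 ** (-self.uptake_interval_min / self.half_life_min)


def to_suv(activity: VolumeGrid, acq: AcquisitionInfo) -> VolumeGrid:
    """Convert a PET activity-concentration volume (Bq/mL) to SUV (unitless).

    SUV(v) = C(v) [Bq/mL] * body_weight [g] / (dose * 2^(-dt/T_half)) [Bq].
    Geometry is unchanged.
    """
    if activity.modality != Modality.PET_ACTIVITY:
        raise ValueError(f"expected PET_ACTIVITY volume, got {activity.modality}")
    scale = acq.body_weight_kg * 1000.0 / acq.decay_corrected_dose_bq
    return activity.with_voxels(np.asarray(activity.voxels, dtype=float) * scale, Modality.PET_SUV)


def resample_isotropic(vol: VolumeGrid, target_spacing: float = 1.0) -> VolumeGrid:
    """Resample to an isotropic grid (default 1 mm).

    Intensity volumes are interpolated trilinearly; MASK volumes use nearest
    neighbor.  The output grid covers the same physical extent (voxel-center
    to voxel-center), keeps the origin, and is exactly the input when the
    input is already at the target spacing.
    """
    if vol.voxels.size == 0:
        raise ValueError("cannot resample an empty volume")
    spacing = np.asarray(vol.spacing, dtype=float)
    if np.allclose(spacing, target_spacing):
        return vol
    extent = (np.asarray(vol.shape) - 1) * spacing
    n_out = np.floor(extent / target_spacing + 1e-9).astype(int) + 1
    coords = [
        np.arange(n) * target_spacing / spacing[ax] for ax, n in enumerate(n_out)
    ]  # fractional input indices along each axis
    mesh = np.meshgrid(*coords, indexing="ij")
    order = 0 if vol.modality == Modality.MASK else 1
    out = map_coordinates(
        np.asarray(vol.voxels, dtype=float), np.stack(mesh), order=order, mode="nearest"
    )
    if vol.modality == Modality.MASK:
        out = np.rint(out).astype(np.int32)
    return VolumeGrid(
        out,
        (target_spacing,) * 3,
        origin=vol.origin,
        modality=vol.modality,
    )


def map_mask_to_ct(mask: VolumeGrid, ct: VolumeGrid) -> VolumeGrid:
    """Transfer a (PET-grid) label mask onto the CT grid by nearest neighbor.

    Both volumes should already be on isotropic grids.  When the grids
    coincide the mask is returned voxel-identical.  Raises if the physical
    extents do not overlap.
    """
    if mask.modality != Modality.MASK:
        raise ValueError("mask must have MASK modality")
    if mask.shape == ct.shape and np.allclose(mask.spacing, ct.spacing) and np.allclose(
        mask.origin, ct.origin
    ):
        return VolumeGrid(np.asarray(mask.voxels).copy(), ct.spacing, ct.origin, Modality.MASK)
    em, ec = mask.physical_extent(), ct.physical_extent()
    if np.any(em[:, 1] < ec[:, 0]) or np.any(ec[:, 1] < em[:, 0]):
        raise ValueError("mask and CT volumes do not overlap in physical space")
    idx = np.indices(ct.shape).astype(float)
    pos = idx * np.asarray(ct.spacing).reshape(3, 1, 1, 1) + np.asarray(ct.origin).reshape(
        3, 1, 1, 1
    )
    src = (pos - np.asarray(mask.origin).reshape(3, 1, 1, 1)) / np.asarray(mask.spacing).reshape(
        3, 1, 1, 1
    )
    src = np.rint(src).astype(int)
    inside = np.all((src >= 0) & (src < np.asarray(mask.shape).reshape(3, 1, 1, 1)), axis=0)
    out = np.zeros(ct.shape, dtype=np.int32)
    src_clipped = np.clip(src, 0, np.asarray(mask.shape).reshape(3, 1, 1, 1) - 1)
    vals = np.asarray(mask.voxels)[tuple(src_clipped)]
    out[inside] = vals[inside]
    return VolumeGrid(out, ct.spacing, ct.origin, Modality.MASK)
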