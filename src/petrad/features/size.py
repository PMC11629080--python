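"""Size-category features (38): volumes, diameters, axis lengths, bounding
box, equivalent-sphere diameter, total lesion glycolysis and
threshold-fraction volumes at fixed fractions of the in-mask maximum."""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from scipy.spatial import ConvexHull
from scipy.spatial.distance import pdist

from .manifest import THRESHOLD_FRACTIONS, size_feature_names
from ._mesh import mask_mesh

__all__ = ["size_features"]


def _surface_voxels(mask: np.ndarray) -> np.ndarray:
    eroded = ndimage.binary_erosion(mask, structure=np.ones((3, 3, 3), dtype=bool))
    surf = mask & ~eroded
    return surf if surf.any() else mask


def _max_pairwise(points: np.ndarray) -> float:
    """Max pairwise distance, via the convex hull when there are many points."""
    if len(points) < 2:
        return 0.0
    if len(points) > 64:
        try:
            points = points[ConvexHull(points).vertices]
        except Exception:  # degenerate (coplanar/collinear) point sets
            pass
    return float(pdist(points).max())


def principal_axis_lengths(mask: np.ndarray, spacing) -> tuple[np.ndarray, np.ndarray]:
    """(eigenvalues desc, axis lengths 4*sqrt(lambda)) of the voxel-center
    coordinate covariance; zero eigenvalues give lengths equal to spacing."""
    coords = np.argwhere(mask) * np.asarray(spacing, dtype=float)
    if len(coords) == 1:
        lam = np.zeros(3)
    else:
        lam = np.sort(np.linalg.eigvalsh(np.cov(coords.T)))[::-1]
        lam = np.maximum(lam, 0.0)
    lengths = 4.0 * np.sqrt(lam)
    fallback = np.sort(np.asarray(spacing, dtype=float))[::-1]
    lengths = np.where(lengths > 1e-9, lengths, fallback)
    return lam, lengths


def size_features(mask: np.ndarray, intensity: np.ndarray, spacing) -> dict[str, float]:
    """All 38 Size features for one lesion.

    ``mask`` boolean, ``intensity`` same-shape scalar volume, ``spacing`` mm.
    Pure-geometry entries depend only on the mask; threshold-fraction volumes
    are relative to the in-mask maximum and hence invariant to intensity
    scaling; total lesion glycolysis = volume_ml * mean intensity.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("size_features requires a nonempty mask")
    spacing = np.asarray(spacing, dtype=float)
    vox_mm3 = float(np.prod(spacing))
    n = int(mask.sum())
    vals = np.asarray(intensity, dtype=float)[mask]
    volume_ml = n * vox_mm3 / 1000.0

    mesh = mask_mesh(mask, spacing)
    coords = np.argwhere(mask) * spacing
    surf = np.argwhere(_surface_voxels(mask)) * spacing

    out: dict[str, float] = {}
    out["voxel_count"] = float(n)
    out["voxel_volume_ml"] = volume_ml
    out["mesh_volume_ml"] = mesh.volume_mm3 / 1000.0
    out["surface_area_mm2"] = mesh.area_mm2
    out["max_3d_diameter_mm"] = _max_pairwise(surf)
    for ax in range(3):
        planes = np.unique(np.argwhere(mask)[:, ax])
        best = 0.0
        for p in planes:
            sl = np.argwhere(_take_plane(mask, ax, p)) * np.delete(spacing, ax)
            best = max(best, _max_pairwise(sl))
        out[f"max_inplane_diameter_ax{ax}_mm"] = best
    _, lengths = principal_axis_lengths(mask, spacing)
    out["major_axis_length_mm"] = float(lengths[0])
    out["minor_axis_length_mm"] = float(lengths[1])
    out["least_axis_length_mm"] = float(lengths[2])
    idx = np.argwhere(mask)
    bbox = (idx.max(axis=0) - idx.min(axis=0) + 1) * spacing
    for ax in range(3):
        out[f"bbox_dim{ax}_mm"] = float(bbox[ax])
    out["bbox_volume_ml"] = float(np.prod(bbox)) / 1000.0
    out["equivalent_sphere_diameter_mm"] = 2.0 * (3.0 * n * vox_mm3 / (4.0 * np.pi)) ** (1 / 3)
    out["total_lesion_glycolysis"] = volume_ml * float(vals.mean())
    centroid = coords.mean(axis=0)
    out["centroid_surface_mean_mm"] = float(np.linalg.norm(surf - centroid, axis=1).mean())
    vmax = float(vals.max())
    for f in THRESHOLD_FRACTIONS:
        above = int((vals >= f * vmax).sum())
        out[f"volume_above_{int(round(f * 100))}pctmax_ml"] = above * vox_mm3 / 1000.0
    for f in THRESHOLD_FRACTIONS:
        above = int((vals >= f * vmax).sum())
        out[f"volume_fraction_above_{int(round(f * 100))}pctmax"] = above / n

    assert list(out) == size_feature_names()
    return out


def _take_plane(mask: np.ndarray, axis: int, index: int) -> np.ndarray:
    sl = [slice(None)] * 3
    sl[axis] = index
    return mask[tuple(sl)]
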