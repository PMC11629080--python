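"""Per-lesion feature extraction: 306 features per modality, 612 combined."""

from __future__ import annotations

import numpy as np
import pandas as pd

from ..grids import VolumeGrid
from .manifest import feature_names
from .shape import shape_features
from .size import size_features
from .texture import discretize, texture_features

__all__ = ["extract_modality", "extract_all", "extract_lesion_set"]

CATEGORY_SELECTORS = ("Size", "Shape", "Texture")


def extract_modality(
    intensity: np.ndarray,
    mask: np.ndarray,
    spacing,
    n_bins: int = 64,
    categories: tuple[str, ...] = CATEGORY_SELECTORS,
) -> dict[str, float]:
    """One modality's features for one lesion, in manifest order.

    ``categories`` restricts extraction (e.g. shape-only) — the full manifest
    requires all three.
    """
    out: dict[str, float] = {}
    if "Size" in categories:
        out.update(size_features(mask, intensity, spacing))
    if "Shape" in categories:
        out.update(shape_features(mask, spacing))
    if "Texture" in categories:
        out.update(texture_features(discretize(intensity, mask, n_bins)))
    return out


def extract_all(
    ct: VolumeGrid,
    pet_suv: VolumeGrid,
    mask: np.ndarray,
    n_bins: int = 64,
    categories: tuple[str, ...] = CATEGORY_SELECTORS,
) -> dict[str, float]:
    """CT_/PET_-prefixed concatenation (612 values for the full manifest).

    ``mask`` is the refined lesion mask on the shared 1-mm grid; shape
    features depend only on the mask and are identical between modalities.
    """
    if ct.shape != pet_suv.shape or not np.allclose(ct.spacing, pet_suv.spacing):
        raise ValueError("CT and PET volumes must share one grid")
    ct_f = extract_modality(np.asarray(ct.voxels), mask, ct.spacing, n_bins, categories)
    pet_f = extract_modality(np.asarray(pet_suv.voxels), mask, pet_suv.spacing, n_bins, categories)
    out = {f"CT_{k}": v for k, v in ct_f.items()}
    out.update({f"PET_{k}": v for k, v in pet_f.items()})
    return out


def extract_lesion_set(
    ct: VolumeGrid,
    pet_suv: VolumeGrid,
    lesions,
    patient_id: str = "",
    n_bins: int = 64,
    categories: tuple[str, ...] = CATEGORY_SELECTORS,
) -> pd.DataFrame:
    """Feature rows (one per lesion) for a segmented patient."""
    labels = np.asarray(lesions.label_volume.voxels)
    rows = []
    for _, lesion in lesions.table.iterrows():
        lid = int(lesion["lesion_id"])
        feats = extract_all(ct, pet_suv, labels == lid, n_bins, categories)
        row = {"patient_id": patient_id, "lesion_id": lid,
               "site_label": lesion["site_label"], "nodal": lesion["nodal"]}
        row.update(feats)
        rows.append(row)
    cols = ["patient_id", "lesion_id", "site_label", "nodal"]
    if rows:
        cols += [k for k in rows[0] if k not in cols]
    return pd.DataFrame(rows, columns=cols)
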