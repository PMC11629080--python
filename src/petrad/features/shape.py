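"""Shape-category features (9): mask-only descriptors of how far a lesion
departs from a sphere.

With mesh volume V and surface area A:

* sphericity            = pi^(1/3) (6V)^(2/3) / A          (ball -> 1)
* compactness1          = V / (sqrt(pi) A^(3/2))
* compactness2          = 36 pi V^2 / A^3
* spherical disproportion = 1 / sphericity
* surface/volume ratio  = A / V                            (1/mm)
* elongation            = sqrt(lambda2 / lambda1)          (PCA eigenvalues)
* flatness              = sqrt(lambda3 / lambda1)
* asphericity           = (A^3 / (36 pi V^2))^(1/3) - 1
* radial irregularity   = SD / mean of surface-voxel distance to centroid
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .manifest import shape_feature_names
from ._mesh import mask_mesh
from .size import principal_axis_lengths

__all__ = ["shape_features"]


def shape_features(mask: np.ndarray, spacing) -> dict[str, float]:
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("shape_features requires a nonempty mask")
    spacing = np.asarray(spacing, dtype=float)
    mesh = mask_mesh(mask, spacing)
    V = max(mesh.volume_mm3, 1e-9)
    A = max(mesh.area_mm2, 1e-9)

    sphericity = np.pi ** (1 / 3) * (6.0 * V) ** (2 / 3) / A
    lam, _ = principal_axis_lengths(mask, spacing)
    lam1 = max(lam[0], 1e-12)
    eroded = ndimage.binary_erosion(mask, structure=np.ones((3, 3, 3), dtype=bool))
    surf = mask & ~eroded
    if not surf.any():
        surf = mask
    coords = np.argwhere(mask) * spacing
    centroid = coords.mean(axis=0)
    d = np.linalg.norm(np.argwhere(surf) * spacing - centroid, axis=1)
    mean_d = d.mean()

    out = {
        "sphericity": float(sphericity),
        "compactness1": float(V / (np.sqrt(np.pi) * A ** 1.5)),
        "compactness2": float(36.0 * np.pi * V**2 / A**3),
        "spherical_disproportion": float(1.0 / sphericity),
        "surface_to_volume_ratio": float(A / V),
        "elongation": float(np.sqrt(max(lam[1], 0.0) / lam1)) if lam[0] > 0 else 1.0,
        "flatness": float(np.sqrt(max(lam[2], 0.0) / lam1)) if lam[0] > 0 else 1.0,
        "asphericity": float((A**3 / (36.0 * np.pi * V**2)) ** (1 / 3) - 1.0),
        "radial_irregularity": float(d.std() / mean_d) if mean_d > 0 else 0.0,
    }
    assert list(out) == shape_feature_names()
    return out
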