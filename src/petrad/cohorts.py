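"""Lesion-level synthetic cohorts for the reduction and modeling stages.

Whole-body phantoms (``petrad.phantom``) exercise segmentation; for the
statistical stages what matters is the chain lesion geometry -> radiomic
features -> principal components -> outcome model.  This module renders each
patient's index lesion in a small local volume of interest at 1 mm,
extracts the requested feature categories, and simulates survival outcomes
from the planted truth — so planted-effect recovery and decoupling
properties can be studied at cohort sizes of hundreds without rendering
hundreds of 128^3 volumes.

Volumes can be held fixed across patients while irregularity varies (the
lobulated surface is rescaled to a target enclosed volume), which is the
construction behind the shape/size decoupling checks.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .features.extract import extract_modality
from .grids import Modality, VolumeGrid
from .phantom import (
    LesionSpec,
    OutcomeModelSpec,
    radius_for_volume,
    rasterize_lesion,
    simulate_outcomes,
    _correlated_field,
)

__all__ = ["render_lesion_voi", "simulate_feature_cohort"]


def render_lesion_voi(
    volume_ml: float,
    irregularity: float,
    seed: int,
    spacing: float = 1.0,
    suv_peak: float = 6.0,
    texture_amp: float = 0.12,
    texture_corr_length: float = 4.0,
    noise_sd: float = 0.05,
    with_texture: bool = True,
    fix_volume: bool = True,
):
    """Render one lesion in a tight local grid.

    Returns ``(ct, pet, mask)``: co-registered CT/PET VolumeGrids and the
    boolean truth mask.  When ``fix_volume`` the base radius is rescaled so
    the enclosed (continuous) volume equals ``volume_ml`` regardless of
    irregularity; otherwise ``volume_ml`` sets the radius of the unperturbed
    ball.
    """
    rng = np.random.default_rng(seed)
    if fix_volume:
        base_radius = radius_for_volume(volume_ml, irregularity, seed)
    else:
        base_radius = (3.0 * volume_ml * 1000.0 / (4.0 * np.pi)) ** (1.0 / 3.0)
    rmax = base_radius * (1.0 + irregularity)
    margin = 3.0 * spacing
    half = rmax + margin
    n = int(np.ceil(2.0 * half / spacing)) + 1
    center = ((n - 1) / 2.0 * spacing,) * 3
    grid = VolumeGrid(np.zeros((n, n, n)), (spacing,) * 3, modality=Modality.PET_SUV)
    def _rasterize(radius: float) -> np.ndarray:
        spec = LesionSpec(
            center=center,
            base_radius=radius,
            irregularity=irregularity,
            suv_peak=suv_peak,
            texture_corr_length=texture_corr_length,
            texture_amp=texture_amp,
            seed=seed,
        )
        return rasterize_lesion(spec, grid)

    mask = _rasterize(base_radius)
    if fix_volume:
        # calibrate the discrete voxel count to the target volume, so voxelized
        # volume carries no systematic trend with irregularity
        target = volume_ml * 1000.0 / spacing**3
        for _ in range(6):
            count = int(mask.sum())
            if count == 0 or abs(count - target) / target < 1e-3:
                break
            base_radius *= (target / count) ** (1.0 / 3.0)
            mask = _rasterize(base_radius)
    pet = np.full((n, n, n), 0.4)
    ct = np.full((n, n, n), 30.0)
    if with_texture:
        tex = _correlated_field(mask.shape, texture_corr_length / spacing,
                                np.random.default_rng(seed + 1))
        pet[mask] = np.maximum(suv_peak * (1.0 + texture_amp * tex[mask]), 0.25 * suv_peak)
        ct[mask] = 70.0 + 40.0 * texture_amp * tex[mask]
    else:
        pet[mask] = suv_peak
        ct[mask] = 70.0
    if noise_sd > 0:
        pet += rng.normal(0.0, noise_sd, pet.shape)
        ct += rng.normal(0.0, noise_sd * 40.0, ct.shape)
        pet = np.maximum(pet, 0.0)
    return (
        grid.with_voxels(ct, Modality.CT),
        grid.with_voxels(pet, Modality.PET_SUV),
        mask,
    )


def simulate_feature_cohort(
    n_patients: int,
    seed: int,
    volume_ml_range: tuple[float, float] = (2.0, 60.0),
    fixed_volume_ml: float | None = None,
    irregularity_range: tuple[float, float] = (0.0, 0.5),
    fixed_irregularity: float | None = None,
    categories: tuple[str, ...] = ("Size", "Shape"),
    modalities: tuple[str, ...] = ("PET",),
    spacing: float = 1.0,
    outcome: OutcomeModelSpec | None = None,
    n_bins: int = 64,
):
    """Simulate an n-patient single-lesion cohort and extract features.

    Volumes are log-uniform over ``volume_ml_range`` (or fixed), irregularity
    uniform over ``irregularity_range`` (or fixed).  Returns
    ``(features, cohort)``: a patients x features DataFrame with
    CT_/PET_-prefixed columns plus ``patient_id``/``subcohort``/``mtv_ml``,
    and the outcome table from :func:`petrad.phantom.simulate_outcomes`
    (betas default to 0 when ``outcome`` is None).  Per-patient seeds derive
    from ``seed`` (seed*100003 + i mod 2^31) so cohorts are reproducible and
    extensible.
    """
    rng = np.random.default_rng(seed)
    rows, truths = [], []
    for i in range(n_patients):
        pseed = int((seed * 100003 + i) % (2**31 - 1))
        if fixed_volume_ml is not None:
            vol = float(fixed_volume_ml)
        else:
            lo, hi = volume_ml_range
            vol = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        if fixed_irregularity is not None:
            irr = float(fixed_irregularity)
        else:
            irr = float(rng.uniform(*irregularity_range))
        suv_peak = float(rng.uniform(4.0, 10.0))
        ct, pet, mask = render_lesion_voi(vol, irr, pseed, spacing=spacing, suv_peak=suv_peak)
        vox_ml = ct.voxel_volume_mm3 / 1000.0
        mtv_ml = float(mask.sum()) * vox_ml
        row = {
            "patient_id": f"p{i:04d}",
            "subcohort": "Lymphatic" if i % 2 == 0 else "Extranodal",
            "mtv_ml": mtv_ml,
        }
        for modality in modalities:
            vol_grid = pet if modality == "PET" else ct
            feats = extract_modality(
                np.asarray(vol_grid.voxels), mask, vol_grid.spacing, n_bins, categories
            )
            row.update({f"{modality}_{k}": v for k, v in feats.items()})
        rows.append(row)
        truths.append({"patient_id": row["patient_id"], "true_mtv": mtv_ml,
                       "true_irregularity": irr})
    features = pd.DataFrame(rows)
    model = outcome if outcome is not None else OutcomeModelSpec(seed=seed)
    if model.seed == 0 and seed != 0:
        model = OutcomeModelSpec(
            beta_mtv=model.beta_mtv, beta_shape=model.beta_shape,
            baseline_hazard=model.baseline_hazard, censoring_rate=model.censoring_rate,
            post_progression_mean=model.post_progression_mean, seed=seed,
        )
    cohort = simulate_outcomes(pd.DataFrame(truths), model)
    cohort = cohort.merge(features[["patient_id", "mtv_ml"]], on="patient_id")
    return features, cohort
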