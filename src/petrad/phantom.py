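"""Synthetic PET/CT phantom cohorts with known ground truth.

Real baseline FDG-PET/CT scans of lymphoma patients are institutionally
restricted, so every downstream stage of the pipeline (SUV standardization,
liver-referenced MTV segmentation, radiomics, outcome models) is exercised
on digital phantoms: whole-body-like volumes containing a homogeneous liver
reference region with known mean/SD, physiologic hot regions (brain/bladder
analogs), and lesions with controlled size, shape irregularity, contrast and
intralesional texture.  Outcomes are generated from an exponential
proportional-hazards model whose log-hazard is linear in log(MTV) and in the
planted shape-irregularity parameter, so planted imaging effects propagate
to survival endpoints in a known way.

Lesion surfaces are star-shaped: ``radius(u) = base_radius * (1 +
irregularity * f(u))`` where ``f`` is a fixed-seed smooth zero-mean random
field on the unit sphere (a sum of low-order Legendre ridges), normalized so
``max|f| = 1``.  ``irregularity = 0`` gives a perfect (rasterized) ball and
increasing irregularity monotonically lowers sphericity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.special import eval_legendre

from .grids import Modality, VolumeGrid, save_nifti

__all__ = [
    "ANATOMIC_SITES",
    "LesionSpec",
    "PhantomSpec",
    "OutcomeModelSpec",
    "SphereField",
    "render_lobulated_surface",
    "rasterize_lesion",
    "render_phantom",
    "simulate_outcomes",
    "make_phantom_spec",
    "write_fixture_cohort",
    "COHORT_COLUMNS",
]

#: Anatomic sites used for per-lesion labels (nodal and extranodal compartments).
ANATOMIC_SITES = (
    "abdomen", "pelvis", "mediastinum", "neck", "lungs", "axilla", "inguinal",
    "musculoskeletal", "liver", "spleen", "skin", "legs", "bone", "chest_wall",
    "head", "kidney", "adrenal", "stomach", "bowel", "soft_tissue",
)

COHORT_COLUMNS = [
    "patient_id", "one_year_event", "os_time", "os_event",
    "pfs_time", "pfs_event", "ldh",
]


@dataclass
class LesionSpec:
    """Geometric and uptake description of one planted lesion."""

    center: tuple[float, float, float]  # mm
    base_radius: float                  # mm
    irregularity: float = 0.0           # >= 0; amplitude of radial perturbation
    suv_peak: float = 6.0
    texture_corr_length: float = 4.0    # mm; correlation length of intralesional field
    texture_amp: float = 0.12           # relative SD of the multiplicative field
    nodal: bool = True
    site_label: str = "abdomen"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.base_radius <= 0:
            raise ValueError("base_radius must be > 0")
        if self.irregularity < 0:
            raise ValueError("irregularity must be >= 0")
        if self.site_label not in ANATOMIC_SITES:
            raise ValueError(f"unknown site_label {self.site_label!r}")


@dataclass
class PhantomSpec:
    """Full description of one synthetic whole-body PET/CT scan."""

    grid_shape: tuple[int, int, int] = (128, 128, 128)
    spacing: tuple[float, float, float] = (2.0, 2.0, 2.0)  # mm
    background_suv: float = 0.4
    liver_center: tuple[float, float, float] = (80.0, 90.0, 150.0)
    liver_radii: tuple[float, float, float] = (45.0, 35.0, 30.0)
    liver_mean: float = 2.0
    liver_sd: float = 0.25
    physiologic_regions: tuple[tuple[tuple[float, float, float], float, float], ...] = ()
    lesions: tuple[LesionSpec, ...] = ()
    noise_sd: float = 0.05
    ct_background_hu: float = 30.0
    ct_lesion_hu: float = 70.0
    ct_liver_hu: float = 55.0
    ct_noise_sd: float = 8.0
    seed: int = 0

    @property
    def detection_threshold(self) -> float:
        """Liver mean + 2 SD — the candidate-detection SUV threshold."""
        return self.liver_mean + 2.0 * self.liver_sd


@dataclass
class OutcomeModelSpec:
    """Exponential proportional-hazards outcome generator.

    log hazard = log(baseline_hazard) + beta_mtv*log(MTV mL) + beta_shape*irregularity.
    Setting both betas to 0 makes outcome independent of imaging.
    """

    beta_mtv: float = 0.0
    beta_shape: float = 0.0
    baseline_hazard: float = 0.03   # events per month
    censoring_rate: float = 0.01    # per month; 0 disables censoring
    post_progression_mean: float = 6.0  # months from progression to death
    seed: int = 0

    def __post_init__(self) -> None:
        if self.baseline_hazard <= 0:
            raise ValueError("baseline_hazard must be > 0")
        if self.censoring_rate < 0:
            raise ValueError("censoring_rate must be >= 0")


# ---------------------------------------------------------------------------
# Lobulated surfaces


class SphereField:
    """Smooth zero-mean random field on the unit sphere with max|f| = 1.

    Built as a seeded sum of Legendre ridges f(u) = sum_j c_j P_{l_j}(u . d_j)
    with degrees 2-4; each P_l (l >= 1) integrates to zero over the sphere, so
    the field is exactly zero-mean in expectation and smooth everywhere
    (pole-free construction).
    """

    def __init__(self, seed: int, n_terms: int = 6, degrees: tuple[int, ...] = (2, 3, 4)):
        rng = np.random.default_rng(seed)
        d = rng.normal(size=(n_terms, 3))
        self.directions = d / np.linalg.norm(d, axis=1, keepdims=True)
        self.coeffs = rng.normal(size=n_terms)
        self.degrees = np.array([degrees[i % len(degrees)] for i in range(n_terms)])
        # normalize so max|f| = 1 on a dense sample
        u = _fibonacci_sphere(4096)
        vals = self._raw(u)
        self._scale = 1.0 / max(np.abs(vals).max(), 1e-12)

    def _raw(self, u: np.ndarray) -> np.ndarray:
        t = u @ self.directions.T  # (..., n_terms)
        out = np.zeros(t.shape[:-1])
        for j, (c, l) in enumerate(zip(self.coeffs, self.degrees)):
            out += c * eval_legendre(int(l), t[..., j])
        return out

    def __call__(self, u: np.ndarray) -> np.ndarray:
        """Evaluate at unit vectors u of shape (..., 3)."""
        return self._raw(np.asarray(u, dtype=float)) * self._scale


def _fibonacci_sphere(n: int) -> np.ndarray:
    i = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * i / n)
    theta = np.pi * (1 + 5**0.5) * i
    return np.stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)], axis=1
    )


def render_lobulated_surface(base_radius: float, irregularity: float, seed: int):
    """Radial surface function on the unit sphere.

    Returns ``radius(theta, phi)`` (polar angle theta in [0, pi], azimuth phi)
    evaluating ``base_radius * (1 + irregularity * f)`` clipped to stay
    positive.  ``irregularity = 0`` gives the constant function
    ``base_radius``.
    """
    if base_radius <= 0:
        raise ValueError("base_radius must be > 0")
    if irregularity < 0:
        raise ValueError("irregularity must be >= 0")
    f = SphereField(seed)

    def radius(theta, phi):
        theta = np.asarray(theta, dtype=float)
        phi = np.asarray(phi, dtype=float)
        u = np.stack(
            [np.sin(theta) * np.cos(phi), np.sin(theta) * np.sin(phi), np.cos(theta)],
            axis=-1,
        )
        r = base_radius * (1.0 + irregularity * f(u))
        return np.maximum(r, 0.05 * base_radius)

    radius.field = f  # expose for direct checks
    return radius


def surface_volume_ml(base_radius: float, irregularity: float, seed: int, n: int = 4096) -> float:
    """Volume enclosed by the lobulated surface, V = (1/3) * mean(r^3) * 4*pi, in mL."""
    f = SphereField(seed)
    u = _fibonacci_sphere(n)
    r = np.maximum(base_radius * (1.0 + irregularity * f(u)), 0.05 * base_radius)
    return float(4.0 * np.pi / 3.0 * np.mean(r**3) / 1000.0)


def radius_for_volume(target_ml: float, irregularity: float, seed: int) -> float:
    """Base radius giving an enclosed volume of ``target_ml`` at this irregularity."""
    v1 = surface_volume_ml(1.0, irregularity, seed)  # volume scales as base_radius^3
    return float((target_ml / v1) ** (1.0 / 3.0))


def rasterize_lesion(spec: LesionSpec, grid: VolumeGrid) -> np.ndarray:
    """Boolean voxel mask of the lesion on ``grid`` (voxel center inside surface)."""
    spacing = np.asarray(grid.spacing)
    origin = np.asarray(grid.origin)
    c = np.asarray(spec.center, dtype=float)
    rmax = spec.base_radius * (1.0 + spec.irregularity) + max(grid.spacing)
    lo = np.maximum(np.floor((c - rmax - origin) / spacing).astype(int), 0)
    hi = np.minimum(np.ceil((c + rmax - origin) / spacing).astype(int) + 1, grid.shape)
    if np.any(lo >= hi):
        return np.zeros(grid.shape, dtype=bool)
    idx = np.meshgrid(*[np.arange(l, h) for l, h in zip(lo, hi)], indexing="ij")
    pos = np.stack(idx, axis=-1) * spacing + origin
    d = pos - c
    r = np.linalg.norm(d, axis=-1)
    inside = np.zeros(r.shape, dtype=bool)
    central = r < 1e-9
    inside |= central
    if spec.irregularity == 0:
        inside |= r <= spec.base_radius
    else:
        f = SphereField(spec.seed)
        with np.errstate(invalid="ignore", divide="ignore"):
            u = np.where(r[..., None] > 1e-9, d / np.maximum(r[..., None], 1e-9), 0.0)
        surf = np.maximum(
            spec.base_radius * (1.0 + spec.irregularity * f(u)), 0.05 * spec.base_radius
        )
        inside |= r <= surf
    mask = np.zeros(grid.shape, dtype=bool)
    mask[tuple(slice(l, h) for l, h in zip(lo, hi))] = inside
    return mask


# ---------------------------------------------------------------------------
# Whole-phantom rendering


def _check_inside(name: str, center, radius, spec: PhantomSpec) -> None:
    c = np.asarray(center, dtype=float)
    extent = (np.asarray(spec.grid_shape) - 1) * np.asarray(spec.spacing)
    r = np.asarray(radius, dtype=float)
    if np.any(c - r < 0) or np.any(c + r > extent):
        raise ValueError(f"region {name!r} extends outside the grid (extent {extent} mm)")


def _ellipsoid_mask(grid: VolumeGrid, center, radii) -> np.ndarray:
    idx = np.indices(grid.shape).astype(float)
    pos = idx * np.asarray(grid.spacing).reshape(3, 1, 1, 1) + np.asarray(grid.origin).reshape(
        3, 1, 1, 1
    )
    d = (pos - np.asarray(center, dtype=float).reshape(3, 1, 1, 1)) / np.asarray(
        radii, dtype=float
    ).reshape(3, 1, 1, 1)
    return np.sum(d**2, axis=0) <= 1.0


def _correlated_field(shape, corr_length_vox: float, rng) -> np.ndarray:
    """Zero-mean, unit-SD smooth Gaussian field."""
    g = rng.standard_normal(shape)
    if corr_length_vox > 0:
        g = gaussian_filter(g, sigma=corr_length_vox)
    sd = g.std()
    if sd < 1e-12:
        return np.zeros(shape)
    return (g - g.mean()) / sd


def render_phantom(spec: PhantomSpec):
    """Render one phantom to (ct, pet, truth_labels, organ_masks).

    ``truth_labels`` is an integer label volume (0 background, k = lesion k,
    in the order of ``spec.lesions``) together with a per-lesion table; it is
    returned as ``(label_volume: VolumeGrid, lesion_table: DataFrame)``.
    ``organ_masks`` maps region names (liver, physiologic_0, ...) to boolean
    arrays.
    """
    rng = np.random.default_rng(spec.seed)
    grid = VolumeGrid(
        np.zeros(spec.grid_shape, dtype=float), spec.spacing, modality=Modality.PET_SUV
    )
    vox_ml = grid.voxel_volume_mm3 / 1000.0

    _check_inside("liver", spec.liver_center, max(spec.liver_radii), spec)
    liver = _ellipsoid_mask(grid, spec.liver_center, spec.liver_radii)

    pet = np.full(spec.grid_shape, spec.background_suv, dtype=float)
    ct = np.full(spec.grid_shape, spec.ct_background_hu, dtype=float)
    pet[liver] = rng.normal(spec.liver_mean, spec.liver_sd, size=int(liver.sum()))
    ct[liver] = spec.ct_liver_hu

    organ_masks: dict[str, np.ndarray] = {"liver": liver}
    for i, (center, radius, suv) in enumerate(spec.physiologic_regions):
        _check_inside(f"physiologic_{i}", center, radius, spec)
        m = _ellipsoid_mask(grid, center, (radius, radius, radius))
        pet[m] = suv
        organ_masks[f"physiologic_{i}"] = m

    labels = np.zeros(spec.grid_shape, dtype=np.int32)
    rows = []
    for k, les in enumerate(spec.lesions, start=1):
        _check_inside(
            f"lesion_{k}", les.center, les.base_radius * (1 + les.irregularity), spec
        )
        m = rasterize_lesion(les, grid)
        if np.any(m & liver) and les.site_label != "liver":
            raise ValueError(f"lesion_{k} overlaps the liver reference region")
        corr_vox = les.texture_corr_length / float(np.mean(spec.spacing))
        tex = _correlated_field(m.shape, corr_vox, np.random.default_rng(les.seed + 1))
        vals = les.suv_peak * (1.0 + les.texture_amp * tex[m])
        pet[m] = np.maximum(vals, 0.25 * les.suv_peak)
        ct[m] = spec.ct_lesion_hu
        labels[m] = k
        rows.append(
            {
                "lesion_id": k,
                "site_label": les.site_label,
                "nodal": bool(les.nodal),
                "true_volume_ml": float(m.sum() * vox_ml),
                "suv_peak": les.suv_peak,
                "irregularity": les.irregularity,
            }
        )

    if spec.noise_sd > 0:
        pet = pet + rng.normal(0.0, spec.noise_sd, size=spec.grid_shape)
        pet = np.maximum(pet, 0.0)
    if spec.ct_noise_sd > 0:
        ct = ct + rng.normal(0.0, spec.ct_noise_sd, size=spec.grid_shape)

    lesion_table = pd.DataFrame(
        rows,
        columns=[
            "lesion_id", "site_label", "nodal", "true_volume_ml", "suv_peak", "irregularity",
        ],
    )
    truth = (grid.with_voxels(labels, Modality.MASK), lesion_table)
    return grid.with_voxels(ct, Modality.CT), grid.with_voxels(pet), truth, organ_masks


def make_phantom_spec(
    seed: int,
    n_lesions: int | None = None,
    lesion_texture_amp: float = 0.12,
    **overrides,
) -> PhantomSpec:
    """Default study-condition phantom: liver reference, two physiologic hot
    regions (brain/bladder analogs, always above the detection threshold),
    and 1-5 lesions with volumes ~1-100 mL, irregularity 0-0.4 and SUV peaks
    4-10 (all detectable against the liver mean + 2 SD threshold of 2.5)."""
    rng = np.random.default_rng(seed)
    base = PhantomSpec(seed=seed, **{k: v for k, v in overrides.items() if k != "lesions"})
    extent = (np.asarray(base.grid_shape) - 1) * np.asarray(base.spacing)
    physio = (
        ((extent[0] / 2, extent[1] / 2, extent[2] - 30.0), 18.0, 8.0),   # brain analog
        ((extent[0] / 2, extent[1] / 2, 30.0), 14.0, 12.0),              # bladder analog
    )
    if n_lesions is None:
        n_lesions = int(rng.integers(1, 6))
    lesions = []
    tries = 0
    occupied = [(np.asarray(base.liver_center), max(base.liver_radii))]
    occupied += [(np.asarray(c), r) for c, r, _ in physio]
    while len(lesions) < n_lesions and tries < 200:
        tries += 1
        radius = float(np.exp(rng.uniform(np.log(8.0), np.log(28.0))))
        irr = float(rng.uniform(0.0, 0.4))
        rmax = radius * (1 + irr)
        lo, hi = rmax + 6.0, extent - rmax - 6.0
        if np.any(hi <= lo):
            continue
        center = rng.uniform(lo, hi)
        if any(np.linalg.norm(center - c) < rmax + r + 6.0 for c, r in occupied):
            continue
        nodal = bool(rng.random() < 0.6)
        sites = ("abdomen", "pelvis", "mediastinum", "neck", "lungs") if nodal else (
            "lungs", "musculoskeletal", "pelvis", "liver", "spleen", "skin",
        )
        lesions.append(
            LesionSpec(
                center=tuple(center),
                base_radius=radius,
                irregularity=irr,
                suv_peak=float(rng.uniform(4.0, 10.0)),
                texture_amp=lesion_texture_amp,
                nodal=nodal,
                site_label=sites[int(rng.integers(len(sites)))],
                seed=int(rng.integers(2**31 - 1)),
            )
        )
        occupied.append((center, rmax))
    return PhantomSpec(
        seed=seed,
        physiologic_regions=physio,
        lesions=tuple(lesions),
        **{k: v for k, v in overrides.items() if k != "lesions"},
    )


# ---------------------------------------------------------------------------
# Outcomes


def simulate_outcomes(truths, model: OutcomeModelSpec) -> pd.DataFrame:
    """Simulate per-patient survival outcomes from planted imaging truth.

    ``truths``: DataFrame (or list of dicts) with columns ``patient_id``,
    ``true_mtv`` (mL) and ``true_irregularity``.  Progression times are
    exponential with hazard ``baseline * exp(beta_mtv*log(MTV) +
    beta_shape*irregularity)``; death follows progression after an
    independent exponential delay; censoring is independent exponential.
    ``one_year_event`` is progression or death within 12 months.
    Zero-burden patients (MTV = 0) get the baseline hazard (the log-MTV term
    is dropped for that stratum).
    """
    truths = pd.DataFrame(truths)
    rng = np.random.default_rng(model.seed)
    n = len(truths)
    mtv = truths["true_mtv"].to_numpy(dtype=float)
    irr = truths["true_irregularity"].to_numpy(dtype=float)
    log_mtv = np.where(mtv > 0, np.log(np.maximum(mtv, 1e-12)), 0.0)
    hazard = model.baseline_hazard * np.exp(model.beta_mtv * log_mtv + model.beta_shape * irr)
    t_prog = rng.exponential(1.0 / hazard)
    t_death = t_prog + rng.exponential(model.post_progression_mean, size=n)
    if model.censoring_rate > 0:
        c = rng.exponential(1.0 / model.censoring_rate, size=n)
    else:
        c = np.full(n, np.inf)
    pfs_time = np.minimum(t_prog, c)
    pfs_event = t_prog <= c
    os_time = np.minimum(t_death, c)
    os_event = t_death <= c
    ldh = _simulate_ldh(rng, log_mtv)
    out = pd.DataFrame(
        {
            "patient_id": truths["patient_id"].to_numpy(),
            "one_year_event": pfs_event & (pfs_time <= 12.0),
            "os_time": np.maximum(os_time, 1e-3),
            "os_event": os_event,
            "pfs_time": np.maximum(pfs_time, 1e-3),
            "pfs_event": pfs_event,
            "ldh": ldh,
            "true_mtv": mtv,
            "true_irregularity": irr,
        }
    )
    return out


def _simulate_ldh(rng, log_mtv: np.ndarray) -> np.ndarray:
    """Serum LDH (U/L): lognormal with median ~266, mean ~400, mildly
    coupled to log tumor burden."""
    z = 0.3 * (log_mtv - np.mean(log_mtv)) / (np.std(log_mtv) + 1e-12)
    return np.exp(np.log(266.0) + 0.9 * (z + np.sqrt(1 - 0.09) * rng.standard_normal(len(log_mtv))))


# ---------------------------------------------------------------------------
# Fixture cohorts on disk


def write_fixture_cohort(out_dir: str | Path, n_patients: int, seed: int, **phantom_overrides) -> Path:
    """Write an n-patient phantom cohort as NIfTI volumes + a cohort CSV.

    Layout: ``out_dir/patient_XXX/{ct,pet_suv,truth_labels}.nii.gz`` plus
    ``out_dir/cohort.csv``.  Deterministic for a fixed seed (per-patient seed
    = seed + patient index).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    truths = []
    for i in range(n_patients):
        pid = f"patient_{i:03d}"
        pdir = out_dir / pid
        pdir.mkdir(exist_ok=True)
        spec = make_phantom_spec(seed + i, **phantom_overrides)
        ct, pet, (labels, table), _ = render_phantom(spec)
        save_nifti(ct, pdir / "ct.nii.gz")
        save_nifti(pet, pdir / "pet_suv.nii.gz")
        save_nifti(labels, pdir / "truth_labels.nii.gz")
        table.to_csv(pdir / "truth_lesions.csv", index=False)
        irr = (
            float(table.loc[table["true_volume_ml"].idxmax(), "irregularity"])
            if len(table)
            else 0.0
        )
        truths.append(
            {
                "patient_id": pid,
                "true_mtv": float(table["true_volume_ml"].sum()),
                "true_irregularity": irr,
            }
        )
    outcomes = simulate_outcomes(
        pd.DataFrame(truths, columns=["patient_id", "true_mtv", "true_irregularity"])
        if truths
        else pd.DataFrame(columns=["patient_id", "true_mtv", "true_irregularity"]),
        OutcomeModelSpec(beta_mtv=0.3, beta_shape=1.0, seed=seed),
    ) if truths else pd.DataFrame(columns=COHORT_COLUMNS)
    cohort_path = out_dir / "cohort.csv"
    outcomes[COHORT_COLUMNS].to_csv(cohort_path, index=False) if len(outcomes) else pd.DataFrame(
        columns=COHORT_COLUMNS
    ).to_csv(cohort_path, index=False)
    return out_dir
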