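"""Frozen radiomic feature manifest: Size (38), Shape (9), Texture (259).

The manifest is the repository's contract for feature identity and order.
It is generated deterministically here and frozen as
``petrad/data/feature_manifest.json``; a unit test fails on any drift.  The
composition follows IBSI-style definitions: Size couples volume/diameter/
axis/bounding-box measures with threshold-fraction volumes; Shape is nine
mask-only descriptors; Texture is 14 first-order histogram statistics plus
gray-level co-occurrence (GLCM, 10 statistics x 13 unique 3D directions +
directional average), run-length (GLRLM, 6 x 14), size-zone (GLSZM, 16) and
neighborhood gray-tone difference (NGTDM, 5) statistics.
"""

from __future__ import annotations

import json
from importlib import resources

SIZE = "Size"
SHAPE = "Shape"
TEXTURE = "Texture"

CATEGORY_COUNTS = {SIZE: 38, SHAPE: 9, TEXTURE: 259}
TOTAL_PER_MODALITY = 306
TOTAL_BOTH_MODALITIES = 612

#: thresholds (fractions of max intensity) for the Size threshold-volume block
THRESHOLD_FRACTIONS = (0.30, 0.35, 0.40, 0.45, 0.50, 0.55, 0.60, 0.65, 0.70, 0.75)

#: 13 unique 3D direction offsets (one per +/- pair of the 26-neighborhood)
DIRECTIONS: tuple[tuple[int, int, int], ...] = tuple(
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) > (0, 0, 0)
)
assert len(DIRECTIONS) == 13

GLCM_STATS = (
    "joint_energy",
    "contrast",
    "correlation",
    "joint_entropy",
    "inverse_difference_moment",
    "dissimilarity",
    "cluster_shade",
    "cluster_prominence",
    "sum_average",
    "difference_entropy",
)

GLRLM_STATS = (
    "short_run_emphasis",
    "long_run_emphasis",
    "gray_level_nonuniformity",
    "run_length_nonuniformity",
    "run_percentage",
    "high_gray_level_run_emphasis",
)

GLSZM_STATS = (
    "small_area_emphasis",
    "large_area_emphasis",
    "gray_level_nonuniformity",
    "gray_level_nonuniformity_normalized",
    "size_zone_nonuniformity",
    "size_zone_nonuniformity_normalized",
    "zone_percentage",
    "gray_level_variance",
    "zone_variance",
    "zone_entropy",
    "low_gray_level_zone_emphasis",
    "high_gray_level_zone_emphasis",
    "small_area_low_gray_level_emphasis",
    "small_area_high_gray_level_emphasis",
    "large_area_low_gray_level_emphasis",
    "large_area_high_gray_level_emphasis",
)

NGTDM_STATS = ("coarseness", "contrast", "busyness", "complexity", "strength")

FIRST_ORDER_STATS = (
    "mean",
    "variance",
    "skewness",
    "kurtosis",
    "median",
    "minimum",
    "maximum",
    "percentile10",
    "percentile90",
    "interquartile_range",
    "range",
    "energy",
    "entropy",
    "uniformity",
)


def size_feature_names() -> list[str]:
    names = [
        "voxel_count",
        "voxel_volume_ml",
        "mesh_volume_ml",
        "surface_area_mm2",
        "max_3d_diameter_mm",
        "max_inplane_diameter_ax0_mm",
        "max_inplane_diameter_ax1_mm",
        "max_inplane_diameter_ax2_mm",
        "major_axis_length_mm",
        "minor_axis_length_mm",
        "least_axis_length_mm",
        "bbox_dim0_mm",
        "bbox_dim1_mm",
        "bbox_dim2_mm",
        "bbox_volume_ml",
        "equivalent_sphere_diameter_mm",
        "total_lesion_glycolysis",
        "centroid_surface_mean_mm",
    ]
    for f in THRESHOLD_FRACTIONS:
        names.append(f"volume_above_{int(round(f * 100))}pctmax_ml")
    for f in THRESHOLD_FRACTIONS:
        names.append(f"volume_fraction_above_{int(round(f * 100))}pctmax")
    return names


def shape_feature_names() -> list[str]:
    return [
        "sphericity",
        "compactness1",
        "compactness2",
        "spherical_disproportion",
        "surface_to_volume_ratio",
        "elongation",
        "flatness",
        "asphericity",
        "radial_irregularity",
    ]


def texture_feature_names() -> list[str]:
    names = [f"firstorder_{s}" for s in FIRST_ORDER_STATS]
    dir_tags = [f"d{i + 1:02d}" for i in range(len(DIRECTIONS))] + ["avg"]
    for s in GLCM_STATS:
        names += [f"glcm_{s}_{t}" for t in dir_tags]
    for s in GLRLM_STATS:
        names += [f"glrlm_{s}_{t}" for t in dir_tags]
    names += [f"glszm_{s}" for s in GLSZM_STATS]
    names += [f"ngtdm_{s}" for s in NGTDM_STATS]
    return names


def build_manifest(n_bins: int = 64) -> list[dict]:
    """Ordered manifest entries: {name, category, params}."""
    entries: list[dict] = []
    for name in size_feature_names():
        entries.append({"name": name, "category": SIZE, "params": {}})
    for name in shape_feature_names():
        entries.append({"name": name, "category": SHAPE, "params": {}})
    for name in texture_feature_names():
        params: dict = {"n_bins": n_bins}
        for i, d in enumerate(DIRECTIONS):
            if name.endswith(f"_d{i + 1:02d}"):
                params["direction"] = list(d)
        entries.append({"name": name, "category": TEXTURE, "params": params})
    counts = {c: sum(1 for e in entries if e["category"] == c) for c in CATEGORY_COUNTS}
    if counts != CATEGORY_COUNTS or len(entries) != TOTAL_PER_MODALITY:
        raise AssertionError(f"manifest drift: {counts} (total {len(entries)})")
    if len({e["name"] for e in entries}) != len(entries):
        raise AssertionError("manifest names are not unique")
    return entries


def feature_names(category: str | None = None) -> list[str]:
    if category is None:
        return size_feature_names() + shape_feature_names() + texture_feature_names()
    return {
        SIZE: size_feature_names,
        SHAPE: shape_feature_names,
        TEXTURE: texture_feature_names,
    }[category]()


def load_frozen_manifest() -> list[dict]:
    """The manifest JSON shipped with the package."""
    with resources.files("petrad.data").joinpath("feature_manifest.json").open() as fh:
        return json.load(fh)


def category_of(name: str) -> str:
    """Category of a (possibly CT_/PET_-prefixed) feature name."""
    bare = name.split("_", 1)[1] if name.startswith(("CT_", "PET_")) else name
    if bare in _SIZE_SET:
        return SIZE
    if bare in _SHAPE_SET:
        return SHAPE
    if bare in _TEXTURE_SET:
        return TEXTURE
    raise KeyError(f"unknown feature {name!r}")


_SIZE_SET = frozenset(size_feature_names())
_SHAPE_SET = frozenset(shape_feature_names())
_TEXTURE_SET = frozenset(texture_feature_names())
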