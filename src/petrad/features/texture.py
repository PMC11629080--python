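"""Texture-category features (259) from gray-level matrices.

In-mask intensities are discretized into ``G`` equal-width bins (default 64)
over the in-mask [min, max] range.  From the discretized lesion:

* 14 first-order histogram statistics (entropy/uniformity on the G-bin
  histogram, the rest on raw intensities);
* GLCM — symmetric, normalized co-occurrence matrices for the 13 unique 3D
  directions; 10 statistics per direction plus their directional average;
* GLRLM — run-length matrices per direction, 6 statistics + average;
* GLSZM — 26-connected equal-level zones, 16 statistics (rotation
  invariant, no directional expansion);
* NGTDM — neighborhood gray-tone difference statistics (5).

Degenerate inputs follow fixed conventions: a constant lesion has zero
entropy-type features, unit energy/uniformity-type features, and GLCM
correlation is defined as 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .manifest import (
    DIRECTIONS,
    FIRST_ORDER_STATS,
    GLCM_STATS,
    GLRLM_STATS,
    GLSZM_STATS,
    NGTDM_STATS,
    texture_feature_names,
)

__all__ = [
    "DiscretizedLesion",
    "discretize",
    "glcm",
    "glcm_stats",
    "glrlm_matrix",
    "glrlm_stats",
    "glszm_matrix",
    "glszm_stats",
    "ngtdm_stats",
    "first_order_stats",
    "texture_features",
]

_STRUCT26 = np.ones((3, 3, 3), dtype=bool)


@dataclass
class DiscretizedLesion:
    """Bin indices 1..G inside the mask (0 outside)."""

    levels: np.ndarray  # int array, 0 outside mask
    mask: np.ndarray
    n_bins: int
    bin_edges: np.ndarray
    raw: np.ndarray  # raw in-mask intensities (1D)


def discretize(intensity: np.ndarray, mask: np.ndarray, n_bins: int = 64) -> DiscretizedLesion:
    """Equal-width binning of in-mask intensities into 1..n_bins.

    A constant region maps every voxel to bin 1.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("discretize requires a nonempty mask")
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    vals = np.asarray(intensity, dtype=float)[mask]
    lo, hi = float(vals.min()), float(vals.max())
    levels = np.zeros(mask.shape, dtype=np.int32)
    if hi <= lo or n_bins == 1:
        levels[mask] = 1
        edges = np.array([lo, hi if hi > lo else lo + 1.0])
    else:
        edges = np.linspace(lo, hi, n_bins + 1)
        binned = np.minimum(
            np.floor((vals - lo) / (hi - lo) * n_bins).astype(np.int32), n_bins - 1
        )
        levels[mask] = binned + 1
    return DiscretizedLesion(levels=levels, mask=mask, n_bins=n_bins, bin_edges=edges, raw=vals)


# ---------------------------------------------------------------------------
# GLCM


def glcm(d: DiscretizedLesion, offset) -> np.ndarray:
    """Symmetric normalized co-occurrence matrix for one 3D offset.

    Counts in-mask voxel pairs (x, x+offset), symmetrizes, and normalizes to
    sum 1.  Returns the zero matrix when no valid pair exists.
    """
    off = np.asarray(offset, dtype=int)
    G = d.n_bins
    a, b = _shifted_pairs(d.levels, d.mask, off)
    P = np.zeros((G, G), dtype=float)
    if a.size:
        np.add.at(P, (a - 1, b - 1), 1.0)
        P = P + P.T
        P /= P.sum()
    return P


def _shifted_pairs(levels: np.ndarray, mask: np.ndarray, off: np.ndarray):
    """Level pairs (a at x, b at x+off) with both endpoints in the mask."""
    sl_a, sl_b = [], []
    for ax, o in enumerate(off):
        n = levels.shape[ax]
        if o >= 0:
            sl_a.append(slice(0, n - o))
            sl_b.append(slice(o, n))
        else:
            sl_a.append(slice(-o, n))
            sl_b.append(slice(0, n + o))
    va, vb = levels[tuple(sl_a)], levels[tuple(sl_b)]
    ma, mb = mask[tuple(sl_a)], mask[tuple(sl_b)]
    keep = ma & mb
    return va[keep], vb[keep]


def glcm_stats(P: np.ndarray) -> dict[str, float]:
    """The 10 co-occurrence statistics on a normalized symmetric matrix."""
    G = P.shape[0]
    if P.sum() <= 0:
        return {s: (1.0 if s in ("joint_energy", "correlation") else 0.0) for s in GLCM_STATS}
    i = np.arange(1, G + 1, dtype=float)
    I, J = np.meshgrid(i, i, indexing="ij")
    px = P.sum(axis=1)
    mu = float((i * px).sum())
    sigma2 = float(((i - mu) ** 2 * px).sum())
    pos = P > 0
    # difference distribution p_{|i-j|}
    k = np.abs(I - J).astype(int)
    pdiff = np.zeros(G)
    np.add.at(pdiff, k.ravel(), P.ravel())
    pdiff_pos = pdiff[pdiff > 0]
    out = {
        "joint_energy": float((P**2).sum()),
        "contrast": float(((I - J) ** 2 * P).sum()),
        "correlation": float(((I - mu) * (J - mu) * P).sum() / sigma2) if sigma2 > 1e-12 else 1.0,
        "joint_entropy": float(-(P[pos] * np.log2(P[pos])).sum()),
        "inverse_difference_moment": float((P / (1.0 + (I - J) ** 2)).sum()),
        "dissimilarity": float((np.abs(I - J) * P).sum()),
        "cluster_shade": float(((I + J - 2 * mu) ** 3 * P).sum()),
        "cluster_prominence": float(((I + J - 2 * mu) ** 4 * P).sum()),
        "sum_average": float(((I + J) * P).sum()),
        "difference_entropy": float(-(pdiff_pos * np.log2(pdiff_pos)).sum()),
    }
    return out


# ---------------------------------------------------------------------------
# GLRLM


def glrlm_matrix(d: DiscretizedLesion, offset) -> np.ndarray:
    """Run-length matrix R[g-1, l-1]: number of maximal runs of level g with
    length l along the given direction (runs are maximal in-mask stretches of
    constant level)."""
    off = np.asarray(offset, dtype=int)
    levels, mask = d.levels, d.mask
    shape = np.asarray(levels.shape)
    max_len = int(np.abs(off * shape).sum()) + 1
    R = np.zeros((d.n_bins, max_len), dtype=float)
    # run starts: in-mask voxels whose predecessor (x - off) is absent or differs
    prev = _shift_value(levels, -off)
    prev_in = _shift_value(mask.astype(np.int8), -off).astype(bool)
    start = mask & ~(prev_in & (prev == levels))
    pts = np.argwhere(start)
    if pts.size == 0:
        return R[:, :1]
    g = levels[tuple(pts.T)]
    lengths = np.ones(len(pts), dtype=int)
    cur = pts.copy()
    active = np.arange(len(pts))
    while active.size:
        nxt = cur[active] + off
        ok = np.all((nxt >= 0) & (nxt < shape), axis=1)
        if ok.any():
            idx = tuple(nxt[ok].T)
            ok2 = ok.copy()
            ok2[ok] = mask[idx] & (levels[idx] == g[active[ok]])
        else:
            ok2 = ok
        adv = active[ok2]
        lengths[adv] += 1
        cur[adv] += off
        active = adv
    np.add.at(R, (g - 1, lengths - 1), 1.0)
    used = max(int(lengths.max()), 1)
    return R[:, :used]


def _shift_value(arr: np.ndarray, off: np.ndarray) -> np.ndarray:
    """Value at x + off, zero-filled at the boundary."""
    out = np.zeros_like(arr)
    src, dst = [], []
    for ax, o in enumerate(off):
        n = arr.shape[ax]
        if o >= 0:
            src.append(slice(o, n))
            dst.append(slice(0, n - o))
        else:
            src.append(slice(0, n + o))
            dst.append(slice(-o, n))
    out[tuple(dst)] = arr[tuple(src)]
    return out


def glrlm_stats(R: np.ndarray, n_voxels: int) -> dict[str, float]:
    Nr = R.sum()
    if Nr <= 0:
        return {s: 0.0 for s in GLRLM_STATS}
    g = np.arange(1, R.shape[0] + 1, dtype=float)[:, None]
    l = np.arange(1, R.shape[1] + 1, dtype=float)[None, :]
    return {
        "short_run_emphasis": float((R / l**2).sum() / Nr),
        "long_run_emphasis": float((R * l**2).sum() / Nr),
        "gray_level_nonuniformity": float((R.sum(axis=1) ** 2).sum() / Nr),
        "run_length_nonuniformity": float((R.sum(axis=0) ** 2).sum() / Nr),
        "run_percentage": float(Nr / n_voxels),
        "high_gray_level_run_emphasis": float((R * g**2).sum() / Nr),
    }


# ---------------------------------------------------------------------------
# GLSZM


def glszm_matrix(d: DiscretizedLesion) -> np.ndarray:
    """Size-zone matrix S[g-1, s-1]: number of 26-connected zones of level g
    with s voxels."""
    sizes_by_level = []
    max_size = 1
    for g in range(1, d.n_bins + 1):
        m = d.levels == g
        if not m.any():
            sizes_by_level.append(np.array([], dtype=int))
            continue
        lab, n = ndimage.label(m, structure=_STRUCT26)
        sizes = np.bincount(lab.ravel())[1:]
        sizes_by_level.append(sizes)
        max_size = max(max_size, int(sizes.max()))
    S = np.zeros((d.n_bins, max_size), dtype=float)
    for g0, sizes in enumerate(sizes_by_level):
        for s in sizes:
            S[g0, s - 1] += 1.0
    return S


def glszm_stats(S: np.ndarray, n_voxels: int) -> dict[str, float]:
    Nz = S.sum()
    if Nz <= 0:
        return {s: 0.0 for s in GLSZM_STATS}
    g = np.arange(1, S.shape[0] + 1, dtype=float)[:, None]
    s = np.arange(1, S.shape[1] + 1, dtype=float)[None, :]
    p = S / Nz
    pg = p.sum(axis=1)
    ps = p.sum(axis=0)
    mu_g = float((g[:, 0] * pg).sum())
    mu_s = float((s[0, :] * ps).sum())
    ppos = p[p > 0]
    return {
        "small_area_emphasis": float((S / s**2).sum() / Nz),
        "large_area_emphasis": float((S * s**2).sum() / Nz),
        "gray_level_nonuniformity": float((S.sum(axis=1) ** 2).sum() / Nz),
        "gray_level_nonuniformity_normalized": float((S.sum(axis=1) ** 2).sum() / Nz**2),
        "size_zone_nonuniformity": float((S.sum(axis=0) ** 2).sum() / Nz),
        "size_zone_nonuniformity_normalized": float((S.sum(axis=0) ** 2).sum() / Nz**2),
        "zone_percentage": float(Nz / n_voxels),
        "gray_level_variance": float((pg * (g[:, 0] - mu_g) ** 2).sum()),
        "zone_variance": float((ps * (s[0, :] - mu_s) ** 2).sum()),
        "zone_entropy": float(-(ppos * np.log2(ppos)).sum()),
        "low_gray_level_zone_emphasis": float((S / g**2).sum() / Nz),
        "high_gray_level_zone_emphasis": float((S * g**2).sum() / Nz),
        "small_area_low_gray_level_emphasis": float((S / (s**2 * g**2)).sum() / Nz),
        "small_area_high_gray_level_emphasis": float((S * g**2 / s**2).sum() / Nz),
        "large_area_low_gray_level_emphasis": float((S * s**2 / g**2).sum() / Nz),
        "large_area_high_gray_level_emphasis": float((S * s**2 * g**2).sum() / Nz),
    }


# ---------------------------------------------------------------------------
# NGTDM


def ngtdm_stats(d: DiscretizedLesion) -> dict[str, float]:
    """Neighborhood gray-tone difference statistics.

    For each in-mask voxel, the mean level of its in-mask 26-neighbors is
    compared with its own level; s_i sums |i - mean| over voxels of level i.
    """
    levels = d.levels.astype(float)
    inm = d.mask.astype(float)
    kernel = np.ones((3, 3, 3))
    kernel[1, 1, 1] = 0.0
    nb_sum = ndimage.convolve(levels * inm, kernel, mode="constant")
    nb_cnt = ndimage.convolve(inm, kernel, mode="constant")
    valid = d.mask & (nb_cnt > 0)
    N = int(valid.sum())
    G = d.n_bins
    n_i = np.zeros(G)
    s_i = np.zeros(G)
    lv = d.levels[valid]
    diff = np.abs(lv - nb_sum[valid] / nb_cnt[valid])
    np.add.at(n_i, lv - 1, 1.0)
    np.add.at(s_i, lv - 1, diff)
    if N == 0:
        return {s: 0.0 for s in NGTDM_STATS}
    p_i = n_i / N
    present = p_i > 0
    Ngp = int(present.sum())
    i_vals = np.arange(1, G + 1, dtype=float)
    ps = float((p_i * s_i).sum())
    coarseness = 1.0 / ps if ps > 1e-12 else 1e6
    ii, jj = np.meshgrid(i_vals[present], i_vals[present], indexing="ij")
    pi, pj = np.meshgrid(p_i[present], p_i[present], indexing="ij")
    si, sj = np.meshgrid(s_i[present], s_i[present], indexing="ij")
    if Ngp > 1:
        contrast = float((pi * pj * (ii - jj) ** 2).sum() / (Ngp * (Ngp - 1)) * s_i.sum() / N)
        denom_b = float(np.abs(ii * pi - jj * pj).sum())
        busyness = ps / denom_b if denom_b > 1e-12 else 0.0
        complexity = float((np.abs(ii - jj) * (pi * si + pj * sj) / (pi + pj)).sum() / N)
        strength = float(((pi + pj) * (ii - jj) ** 2).sum() / ps) if ps > 1e-12 else 0.0
    else:
        contrast = busyness = complexity = strength = 0.0
    return {
        "coarseness": coarseness,
        "contrast": contrast,
        "busyness": busyness,
        "complexity": complexity,
        "strength": strength,
    }


# ---------------------------------------------------------------------------
# First order


def first_order_stats(d: DiscretizedLesion) -> dict[str, float]:
    v = d.raw
    n = v.size
    mean = float(v.mean())
    var = float(v.var())
    sd = np.sqrt(var)
    if sd > 1e-12:
        skew = float(((v - mean) ** 3).mean() / sd**3)
        kurt = float(((v - mean) ** 4).mean() / sd**4)
    else:
        skew, kurt = 0.0, 0.0
    hist = np.bincount(d.levels[d.mask] - 1, minlength=d.n_bins).astype(float)
    p = hist / n
    ppos = p[p > 0]
    return {
        "mean": mean,
        "variance": var,
        "skewness": skew,
        "kurtosis": kurt,
        "median": float(np.median(v)),
        "minimum": float(v.min()),
        "maximum": float(v.max()),
        "percentile10": float(np.percentile(v, 10)),
        "percentile90": float(np.percentile(v, 90)),
        "interquartile_range": float(np.percentile(v, 75) - np.percentile(v, 25)),
        "range": float(v.max() - v.min()),
        "energy": float((v**2).sum()),
        "entropy": float(-(ppos * np.log2(ppos)).sum()),
        "uniformity": float((p**2).sum()),
    }


# ---------------------------------------------------------------------------
# Full texture block


def texture_features(d: DiscretizedLesion) -> dict[str, float]:
    """All 259 texture features, in manifest order.

    Per-direction GLCM/GLRLM statistics carry ``_dNN`` suffixes in the fixed
    direction order; ``_avg`` entries are the arithmetic mean of the 13
    per-direction values.
    """
    n_vox = int(d.mask.sum())
    out: dict[str, float] = {}
    fo = first_order_stats(d)
    for s in FIRST_ORDER_STATS:
        out[f"firstorder_{s}"] = fo[s]

    glcm_per_dir = [glcm_stats(glcm(d, off)) for off in DIRECTIONS]
    for s in GLCM_STATS:
        vals = [gd[s] for gd in glcm_per_dir]
        for i, v in enumerate(vals):
            out[f"glcm_{s}_d{i + 1:02d}"] = v
        out[f"glcm_{s}_avg"] = float(np.mean(vals))

    glrlm_per_dir = [glrlm_stats(glrlm_matrix(d, off), n_vox) for off in DIRECTIONS]
    for s in GLRLM_STATS:
        vals = [gd[s] for gd in glrlm_per_dir]
        for i, v in enumerate(vals):
            out[f"glrlm_{s}_d{i + 1:02d}"] = v
        out[f"glrlm_{s}_avg"] = float(np.mean(vals))

    sz = glszm_stats(glszm_matrix(d), n_vox)
    for s in GLSZM_STATS:
        out[f"glszm_{s}"] = sz[s]
    ng = ngtdm_stats(d)
    for s in NGTDM_STATS:
        out[f"ngtdm_{s}"] = ng[s]

    assert list(out) == texture_feature_names()
    return out
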