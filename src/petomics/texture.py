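"""IBSI-style 3D texture features: intensity histogram, GLCM, NGTDM, GLSZM
and cross-modality (PET/CT fusion) co-occurrence features.

All matrix features are computed on a fixed-bin-number discretization of the
in-mask intensities, with a single merged 3D matrix per lesion:

* GLCM — distance-1 voxel pairs pooled over the 13 unique 3D directions into
  one symmetric matrix before feature computation ("3D merged").
* NGTDM — 26-neighborhood, in-mask neighbors only.
* GLSZM — zones are maximal 26-connected same-bin regions.
* Fusion — the joint distribution of (PET bin, CT bin) over spatially
  co-located in-mask voxels, with GLCM-style statistics on that matrix.

Degenerate inputs (constant lesion, single voxel) return the uniform-image
limit of each feature rather than NaN, so downstream tables stay finite.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import measure

from .volumes import ImageVolume, LesionMask

#: the 13 unique distance-1 direction offsets of the 26-neighborhood
OFFSETS_3D = [
    off
    for off in itertools.product((-1, 0, 1), repeat=3)
    if off > (0, 0, 0)
]

_LOG2_EPS = 0.0  # entropies use the 0·log0 = 0 convention, no epsilon


@dataclass
class DiscretizedVolume:
    """Integer bin image in {1..n_bins} inside the mask, 0 outside."""

    bins: np.ndarray
    mask: np.ndarray
    n_bins: int
    vmin: float
    vmax: float
    degenerate: bool = False

    @property
    def bin_width(self) -> float:
        return (self.vmax - self.vmin) / self.n_bins if self.vmax > self.vmin else 0.0


def discretize(volume: ImageVolume, mask: LesionMask, n_bins: int = 32) -> DiscretizedVolume:
    """Fixed-bin-number discretization over the in-mask intensity range.

    ``bin(v) = min(B, 1 + floor(B (v - min) / (max - min)))`` so bin edges span
    exactly the in-mask range and the maximum maps to bin B. A constant lesion
    maps every voxel to bin 1 and sets the ``degenerate`` flag; texture
    features then take their uniform-image limit values.
    """
    if n_bins < 2:
        raise ValueError("need at least 2 bins")
    m = np.asarray(mask.voxels, dtype=bool)
    if not m.any():
        raise ValueError("empty mask")
    vals = volume.values[m]
    vmin, vmax = float(vals.min()), float(vals.max())
    bins = np.zeros(volume.shape, dtype=np.int64)
    if vmax > vmin:
        b = 1 + np.floor(n_bins * (volume.values[m] - vmin) / (vmax - vmin))
        bins[m] = np.minimum(n_bins, b).astype(np.int64)
        degenerate = False
    else:
        bins[m] = 1
        degenerate = True
    return DiscretizedVolume(bins, m, n_bins, vmin, vmax, degenerate)


# --------------------------------------------------------------------------
# intensity histogram

def histogram_features(d: DiscretizedVolume, raw_in_mask: np.ndarray | None = None) -> dict[str, float]:
    """Histogram statistics of the discretized in-mask intensities.

    Moments are computed on the bin values weighted by their probabilities;
    skewness and kurtosis (excess) fall back to 0 for a degenerate histogram.
    ``intensity_range`` is taken from the raw (pre-discretization) values when
    given.
    """
    levels = np.arange(1, d.n_bins + 1, dtype=np.float64)
    counts = np.bincount(d.bins[d.mask], minlength=d.n_bins + 1)[1:]
    p = counts / counts.sum()
    mean = float((levels * p).sum())
    var = float(((levels - mean) ** 2 * p).sum())
    if var > 0:
        skew = float(((levels - mean) ** 3 * p).sum() / var**1.5)
        kurt = float(((levels - mean) ** 4 * p).sum() / var**2) - 3.0
    else:
        skew, kurt = 0.0, 0.0
    nz = p[p > 0]
    out = {
        "hist_mean": mean,
        "hist_variance": var,
        "hist_skewness": skew,
        "hist_kurtosis": kurt,
        "hist_uniformity": float((p**2).sum()),
        "hist_entropy": float(-(nz * np.log2(nz)).sum()),
    }
    if raw_in_mask is not None:
        out["intensity_range"] = float(np.max(raw_in_mask) - np.min(raw_in_mask))
    return out


# --------------------------------------------------------------------------
# co-occurrence machinery (shared by GLCM and the PET/CT fusion matrix)

def _pairs_for_offset(bins: np.ndarray, mask: np.ndarray, off: tuple[int, int, int]):
    """In-mask value pairs (v[x], v[x+off]) for one direction offset."""
    src = tuple(slice(max(0, -o), n - max(0, o)) for o, n in zip(off, bins.shape))
    dst = tuple(slice(max(0, o), n - max(0, -o)) for o, n in zip(off, bins.shape))
    valid = mask[src] & mask[dst]
    return bins[src][valid], bins[dst][valid]


def glcm_matrix(d: DiscretizedVolume) -> np.ndarray:
    """Merged symmetric 3D co-occurrence matrix, normalized to sum 1.

    Pools distance-1 pairs over all 13 unique directions (each pair counted
    in both orders, making the matrix symmetric). With no valid pair (single
    voxel), the lone voxel's bin gets probability 1 — the uniform-image limit.
    """
    B = d.n_bins
    counts = np.zeros(B * B, dtype=np.float64)
    for off in OFFSETS_3D:
        a, b = _pairs_for_offset(d.bins, d.mask, off)
        if a.size:
            counts += np.bincount((a - 1) * B + (b - 1), minlength=B * B)
    P = counts.reshape(B, B)
    P = P + P.T
    total = P.sum()
    if total == 0:
        lone = int(d.bins[d.mask][0]) - 1
        P[lone, lone] = 1.0
        total = 1.0
    return P / total


def cooccurrence_stats(P: np.ndarray) -> dict[str, float]:
    """Full set of co-occurrence statistics on a (not necessarily symmetric)
    normalized matrix ``P(i, j)`` with levels i, j = 1..B.

    Follows the standard IBSI formulas; degenerate limits: correlation -> 1
    and both information-correlation measures -> 0 when a marginal has zero
    variance or entropy.
    """
    B = P.shape[0]
    i = np.arange(1, B + 1, dtype=np.float64)[:, None]
    j = np.arange(1, B + 1, dtype=np.float64)[None, :]
    px = P.sum(axis=1)
    py = P.sum(axis=0)
    mux = float((np.arange(1, B + 1) * px).sum())
    muy = float((np.arange(1, B + 1) * py).sum())
    sx = float(np.sqrt(((np.arange(1, B + 1) - mux) ** 2 * px).sum()))
    sy = float(np.sqrt(((np.arange(1, B + 1) - muy) ** 2 * py).sum()))

    def _ent(q: np.ndarray) -> float:
        q = q[q > 0]
        return float(-(q * np.log2(q)).sum())

    # diagonal (i+j) and cross-diagonal (|i-j|) marginals
    ipj = (i + j).astype(np.int64)
    imj = np.abs(i - j).astype(np.int64)
    p_sum = np.bincount(ipj.ravel(), weights=P.ravel(), minlength=2 * B + 1)[2:]
    p_diff = np.bincount(imj.ravel(), weights=P.ravel(), minlength=B)
    ks = np.arange(2, 2 * B + 1, dtype=np.float64)
    kd = np.arange(0, B, dtype=np.float64)

    sum_avg = float((ks * p_sum).sum())
    diff_avg = float((kd * p_diff).sum())
    hxy = _ent(P.ravel())
    pxy_outer = px[:, None] * py[None, :]
    with np.errstate(divide="ignore"):
        log_outer = np.where(pxy_outer > 0, np.log2(np.where(pxy_outer > 0, pxy_outer, 1.0)), 0.0)
    hxy1 = float(-(P * log_outer).sum())
    hxy2 = _ent(pxy_outer.ravel())
    hx = _ent(px)
    hy = _ent(py)

    corr = float((P * i * j).sum() - mux * muy)
    corr = corr / (sx * sy) if sx > 0 and sy > 0 else 1.0
    denom_ic1 = max(hx, hy)
    ic1 = (hxy - hxy1) / denom_ic1 if denom_ic1 > 0 else 0.0
    ic2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - hxy))))) if hxy2 >= hxy else 0.0

    c = i + j - mux - muy
    return {
        "joint_maximum": float(P.max()),
        "joint_average": float((P * i).sum()),
        "joint_variance": float((P * (i - (P * i).sum()) ** 2).sum()),
        "joint_entropy": hxy,
        "energy": float((P**2).sum()),
        "contrast": float((P * (i - j) ** 2).sum()),
        "dissimilarity": float((P * np.abs(i - j)).sum()),
        "inverse_difference": float((P / (1.0 + np.abs(i - j))).sum()),
        "inverse_difference_moment": float((P / (1.0 + (i - j) ** 2)).sum()),
        "correlation": corr,
        "autocorrelation": float((P * i * j).sum()),
        "cluster_tendency": float((P * c**2).sum()),
        "cluster_shade": float((P * c**3).sum()),
        "cluster_prominence": float((P * c**4).sum()),
        "sum_average": sum_avg,
        "sum_variance": float(((ks - sum_avg) ** 2 * p_sum).sum()),
        "sum_entropy": _ent(p_sum),
        "difference_average": diff_avg,
        "difference_variance": float(((kd - diff_avg) ** 2 * p_diff).sum()),
        "difference_entropy": _ent(p_diff),
        "information_correlation_1": float(ic1),
        "information_correlation_2": float(ic2),
    }


GLCM_FEATURES = [
    "joint_maximum", "joint_average", "joint_variance", "joint_entropy",
    "energy", "contrast", "dissimilarity", "inverse_difference",
    "inverse_difference_moment", "correlation", "autocorrelation",
    "cluster_tendency", "cluster_shade", "cluster_prominence",
    "sum_average", "sum_variance", "sum_entropy", "difference_average",
    "difference_variance", "difference_entropy",
    "information_correlation_1", "information_correlation_2",
]


def glcm_features(d: DiscretizedVolume) -> dict[str, float]:
    stats = cooccurrence_stats(glcm_matrix(d))
    return {f"glcm_{k}": stats[k] for k in GLCM_FEATURES}


# --------------------------------------------------------------------------
# NGTDM

def ngtdm_matrix(d: DiscretizedVolume) -> tuple[np.ndarray, np.ndarray, int]:
    """Per-level occurrence counts n_i and summed absolute differences s_i.

    For each in-mask voxel with at least one in-mask 26-neighbor, the
    difference between its bin and the mean bin of those neighbors is
    accumulated into s at the voxel's level. Returns (n, s, N_valid) with
    n, s indexed by level 1..B at positions 1..B.
    """
    kernel = np.ones((3, 3, 3))
    kernel[1, 1, 1] = 0.0
    m = d.mask.astype(np.float64)
    nbr_sum = ndimage.correlate(d.bins * m, kernel, mode="constant", cval=0.0)
    nbr_cnt = ndimage.correlate(m, kernel, mode="constant", cval=0.0)
    valid = d.mask & (nbr_cnt > 0)
    levels = d.bins[valid]
    diffs = np.abs(levels - nbr_sum[valid] / nbr_cnt[valid])
    B = d.n_bins
    n = np.bincount(levels, minlength=B + 1).astype(np.float64)
    s = np.bincount(levels, weights=diffs, minlength=B + 1)
    return n, s, int(valid.sum())


def ngtdm_features(d: DiscretizedVolume) -> dict[str, float]:
    """Coarseness, contrast, busyness, complexity, strength.

    A mask with no valid voxel (single voxel, no neighbors) returns all
    features as 0 by convention; coarseness is capped at 1e6 when the
    normalizing sum vanishes (uniform image).
    """
    n, s, N = ngtdm_matrix(d)
    zero = {f"ngtdm_{k}": 0.0 for k in ("coarseness", "contrast", "busyness", "complexity", "strength")}
    if N == 0:
        return zero
    p = n / N
    present = np.flatnonzero(p > 0)
    ii = present.astype(np.float64)
    pi, si = p[present], s[present]
    Ngp = present.size

    ps = float((pi * si).sum())
    coarseness = 1.0 / ps if ps > 0 else 1e6

    if Ngp > 1:
        dij2 = (ii[:, None] - ii[None, :]) ** 2
        contrast = float((pi[:, None] * pi[None, :] * dij2).sum()) / (Ngp * (Ngp - 1)) * float(s.sum()) / N
        busy_den = float(np.abs(ii[:, None] * pi[:, None] - ii[None, :] * pi[None, :]).sum())
        busyness = ps / busy_den if busy_den > 0 else 0.0
        dij = np.abs(ii[:, None] - ii[None, :])
        complexity = float(
            (dij * (pi[:, None] * si[:, None] + pi[None, :] * si[None, :]) / (pi[:, None] + pi[None, :])).sum()
        ) / N
        s_tot = float(s.sum())
        strength = float(((pi[:, None] + pi[None, :]) * dij2).sum()) / s_tot if s_tot > 0 else 0.0
    else:
        contrast = busyness = complexity = strength = 0.0

    return {
        "ngtdm_coarseness": coarseness,
        "ngtdm_contrast": contrast,
        "ngtdm_busyness": busyness,
        "ngtdm_complexity": complexity,
        "ngtdm_strength": strength,
    }


# --------------------------------------------------------------------------
# GLSZM

def glszm_matrix(d: DiscretizedVolume) -> np.ndarray:
    """Zone matrix m(g, s): number of 26-connected zones of level g, size s.

    Indexed [1..B, 1..max_zone] at those positions (row/col 0 unused).
    """
    max_size = int(d.mask.sum())
    M = np.zeros((d.n_bins + 1, max_size + 1), dtype=np.float64)
    for g in np.unique(d.bins[d.mask]):
        lab, nlab = measure.label(
            (d.bins == g) & d.mask, connectivity=3, return_num=True
        )
        if nlab:
            sizes = np.bincount(lab.ravel())[1:]
            M[g] += np.bincount(sizes, minlength=max_size + 1)
    return M


GLSZM_FEATURES = [
    "small_zone_emphasis", "large_zone_emphasis",
    "low_gray_level_emphasis", "high_gray_level_emphasis",
    "small_zone_low_gray_level_emphasis", "small_zone_high_gray_level_emphasis",
    "large_zone_low_gray_level_emphasis", "large_zone_high_gray_level_emphasis",
    "gray_level_nonuniformity", "gray_level_nonuniformity_normalized",
    "zone_size_nonuniformity", "zone_size_nonuniformity_normalized",
    "zone_percentage", "zone_size_entropy",
]


def glszm_features(d: DiscretizedVolume) -> dict[str, float]:
    M = glszm_matrix(d)
    Ns = M.sum()  # number of zones (>= 1 for a nonempty mask)
    Nv = int(d.mask.sum())
    g = np.arange(M.shape[0], dtype=np.float64)[:, None]
    z = np.arange(M.shape[1], dtype=np.float64)[None, :]
    with np.errstate(divide="ignore"):
        g2 = np.where(g > 0, g**2, 1.0)
        z2 = np.where(z > 0, z**2, 1.0)
    mg = M.sum(axis=1)
    mz = M.sum(axis=0)
    p = M / Ns
    nzp = p[p > 0]
    return {
        "glszm_small_zone_emphasis": float((M / z2).sum() / Ns),
        "glszm_large_zone_emphasis": float((M * z**2).sum() / Ns),
        "glszm_low_gray_level_emphasis": float((M / g2).sum() / Ns),
        "glszm_high_gray_level_emphasis": float((M * g**2).sum() / Ns),
        "glszm_small_zone_low_gray_level_emphasis": float((M / (g2 * z2)).sum() / Ns),
        "glszm_small_zone_high_gray_level_emphasis": float((M * g**2 / z2).sum() / Ns),
        "glszm_large_zone_low_gray_level_emphasis": float((M * z**2 / g2).sum() / Ns),
        "glszm_large_zone_high_gray_level_emphasis": float((M * g**2 * z**2).sum() / Ns),
        "glszm_gray_level_nonuniformity": float((mg**2).sum() / Ns),
        "glszm_gray_level_nonuniformity_normalized": float((mg**2).sum() / Ns**2),
        "glszm_zone_size_nonuniformity": float((mz**2).sum() / Ns),
        "glszm_zone_size_nonuniformity_normalized": float((mz**2).sum() / Ns**2),
        "glszm_zone_percentage": float(Ns / Nv),
        "glszm_zone_size_entropy": float(-(nzp * np.log2(nzp)).sum()),
    }


# --------------------------------------------------------------------------
# PET/CT fusion

def fusion_matrix(pet_d: DiscretizedVolume, ct_d: DiscretizedVolume) -> np.ndarray:
    """Cross-modality co-occurrence M(i, j) = P(PET bin i AND CT bin j) for
    spatially co-located in-mask voxels. Requires both images discretized on
    the same grid with the same bin count."""
    if pet_d.bins.shape != ct_d.bins.shape:
        raise ValueError("PET and CT grids differ; resample CT to the PET grid first")
    if pet_d.n_bins != ct_d.n_bins:
        raise ValueError("PET and CT must use the same bin count for fusion")
    m = pet_d.mask
    B = pet_d.n_bins
    idx = (pet_d.bins[m] - 1) * B + (ct_d.bins[m] - 1)
    M = np.bincount(idx, minlength=B * B).reshape(B, B).astype(np.float64)
    return M / M.sum()


FUSION_FEATURES = [
    "joint_maximum", "energy", "joint_entropy", "contrast", "dissimilarity",
    "correlation", "autocorrelation", "cluster_shade", "cluster_prominence",
    "sum_average", "sum_entropy", "difference_entropy",
    "information_correlation_1", "inverse_difference",
]


def fusion_features(pet_d: DiscretizedVolume, ct_d: DiscretizedVolume) -> dict[str, float]:
    stats = cooccurrence_stats(fusion_matrix(pet_d, ct_d))
    return {f"fusion_{k}": stats[k] for k in FUSION_FEATURES}
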