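"""Independent brute-force oracles for the texture features.

Everything here is written as literal, loop-based translations of the
matrix definitions — voxel-pair enumeration for co-occurrence, per-voxel
neighborhood averaging for NGTDM, breadth-first flood fill for size zones —
so it shares no code path with the vectorized implementations it checks.
"""

from __future__ import annotations

import math
from collections import deque

import numpy as np

ALL_26 = [
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) != (0, 0, 0)
]


def oracle_glcm_matrix(bins: np.ndarray, mask: np.ndarray, B: int) -> np.ndarray:
    """Pairwise enumeration over all 26 direction offsets (equivalent to the
    13 unique offsets counted symmetrically)."""
    P = np.zeros((B, B))
    nx, ny, nz = bins.shape
    for x in range(nx):
        for y in range(ny):
            for z in range(nz):
                if not mask[x, y, z]:
                    continue
                for dx, dy, dz in ALL_26:
                    u, v, w = x + dx, y + dy, z + dz
                    if 0 <= u < nx and 0 <= v < ny and 0 <= w < nz and mask[u, v, w]:
                        P[bins[x, y, z] - 1, bins[u, v, w] - 1] += 1
    total = P.sum()
    if total == 0:
        lone = bins[mask][0] - 1
        P[lone, lone] = 1.0
        total = 1.0
    return P / total


def oracle_cooccurrence_stats(P: np.ndarray) -> dict[str, float]:
    B = P.shape[0]
    levels = list(range(1, B + 1))
    px = [sum(P[i - 1][j - 1] for j in levels) for i in levels]
    py = [sum(P[i - 1][j - 1] for i in levels) for j in levels]
    mux = sum(i * px[i - 1] for i in levels)
    muy = sum(j * py[j - 1] for j in levels)
    sx = math.sqrt(sum((i - mux) ** 2 * px[i - 1] for i in levels))
    sy = math.sqrt(sum((j - muy) ** 2 * py[j - 1] for j in levels))

    def ent(values):
        return -sum(v * math.log2(v) for v in values if v > 0)

    p_sum = {}
    p_diff = {}
    for i in levels:
        for j in levels:
            p_sum[i + j] = p_sum.get(i + j, 0.0) + P[i - 1][j - 1]
            p_diff[abs(i - j)] = p_diff.get(abs(i - j), 0.0) + P[i - 1][j - 1]
    sum_avg = sum(k * v for k, v in p_sum.items())
    diff_avg = sum(k * v for k, v in p_diff.items())

    hxy = ent(P.ravel())
    hxy1 = -sum(
        P[i - 1][j - 1] * math.log2(px[i - 1] * py[j - 1])
        for i in levels for j in levels
        if P[i - 1][j - 1] > 0 and px[i - 1] * py[j - 1] > 0
    )
    hxy2 = ent([px[i - 1] * py[j - 1] for i in levels for j in levels])
    hx, hy = ent(px), ent(py)

    joint_avg = sum(i * P[i - 1][j - 1] for i in levels for j in levels)
    acor = sum(i * j * P[i - 1][j - 1] for i in levels for j in levels)
    corr = (acor - mux * muy) / (sx * sy) if sx > 0 and sy > 0 else 1.0
    ic1 = (hxy - hxy1) / max(hx, hy) if max(hx, hy) > 0 else 0.0
    ic2 = math.sqrt(max(0.0, 1.0 - math.exp(-2.0 * (hxy2 - hxy)))) if hxy2 >= hxy else 0.0

    def csum(power):
        return sum(
            (i + j - mux - muy) ** power * P[i - 1][j - 1]
            for i in levels for j in levels
        )

    return {
        "joint_maximum": max(P[i - 1][j - 1] for i in levels for j in levels),
        "joint_average": joint_avg,
        "joint_variance": sum(
            (i - joint_avg) ** 2 * P[i - 1][j - 1] for i in levels for j in levels
        ),
        "joint_entropy": hxy,
        "energy": sum(P[i - 1][j - 1] ** 2 for i in levels for j in levels),
        "contrast": sum((i - j) ** 2 * P[i - 1][j - 1] for i in levels for j in levels),
        "dissimilarity": sum(abs(i - j) * P[i - 1][j - 1] for i in levels for j in levels),
        "inverse_difference": sum(
            P[i - 1][j - 1] / (1 + abs(i - j)) for i in levels for j in levels
        ),
        "inverse_difference_moment": sum(
            P[i - 1][j - 1] / (1 + (i - j) ** 2) for i in levels for j in levels
        ),
        "correlation": corr,
        "autocorrelation": acor,
        "cluster_tendency": csum(2),
        "cluster_shade": csum(3),
        "cluster_prominence": csum(4),
        "sum_average": sum_avg,
        "sum_variance": sum((k - sum_avg) ** 2 * v for k, v in p_sum.items()),
        "sum_entropy": ent(p_sum.values()),
        "difference_average": diff_avg,
        "difference_variance": sum((k - diff_avg) ** 2 * v for k, v in p_diff.items()),
        "difference_entropy": ent(p_diff.values()),
        "information_correlation_1": ic1,
        "information_correlation_2": ic2,
    }


def oracle_ngtdm_features(bins: np.ndarray, mask: np.ndarray, B: int) -> dict[str, float]:
    nx, ny, nz = bins.shape
    n = [0.0] * (B + 1)
    s = [0.0] * (B + 1)
    N = 0
    for x in range(nx):
        for y in range(ny):
            for z in range(nz):
                if not mask[x, y, z]:
                    continue
                nbrs = []
                for dx, dy, dz in ALL_26:
                    u, v, w = x + dx, y + dy, z + dz
                    if 0 <= u < nx and 0 <= v < ny and 0 <= w < nz and mask[u, v, w]:
                        nbrs.append(bins[u, v, w])
                if nbrs:
                    N += 1
                    level = bins[x, y, z]
                    n[level] += 1
                    s[level] += abs(level - sum(nbrs) / len(nbrs))
    zero = {f"ngtdm_{k}": 0.0
            for k in ("coarseness", "contrast", "busyness", "complexity", "strength")}
    if N == 0:
        return zero
    p = [ni / N for ni in n]
    present = [i for i in range(1, B + 1) if p[i] > 0]
    Ngp = len(present)
    ps = sum(p[i] * s[i] for i in present)
    coarseness = 1.0 / ps if ps > 0 else 1e6
    if Ngp > 1:
        contrast = (
            sum(p[i] * p[j] * (i - j) ** 2 for i in present for j in present)
            / (Ngp * (Ngp - 1)) * sum(s) / N
        )
        busy_den = sum(abs(i * p[i] - j * p[j]) for i in present for j in present)
        busyness = ps / busy_den if busy_den > 0 else 0.0
        complexity = sum(
            abs(i - j) * (p[i] * s[i] + p[j] * s[j]) / (p[i] + p[j])
            for i in present for j in present
        ) / N
        stot = sum(s)
        strength = (
            sum((p[i] + p[j]) * (i - j) ** 2 for i in present for j in present) / stot
            if stot > 0 else 0.0
        )
    else:
        contrast = busyness = complexity = strength = 0.0
    return {
        "ngtdm_coarseness": coarseness,
        "ngtdm_contrast": contrast,
        "ngtdm_busyness": busyness,
        "ngtdm_complexity": complexity,
        "ngtdm_strength": strength,
    }


def oracle_glszm_matrix(bins: np.ndarray, mask: np.ndarray, B: int) -> np.ndarray:
    """Zones by breadth-first flood fill with 26-connectivity."""
    nx, ny, nz = bins.shape
    visited = np.zeros_like(mask, dtype=bool)
    max_size = int(mask.sum())
    M = np.zeros((B + 1, max_size + 1))
    for x in range(nx):
        for y in range(ny):
            for z in range(nz):
                if not mask[x, y, z] or visited[x, y, z]:
                    continue
                level = bins[x, y, z]
                size = 0
                queue = deque([(x, y, z)])
                visited[x, y, z] = True
                while queue:
                    cx, cy, cz = queue.popleft()
                    size += 1
                    for dx, dy, dz in ALL_26:
                        u, v, w = cx + dx, cy + dy, cz + dz
                        if (
                            0 <= u < nx and 0 <= v < ny and 0 <= w < nz
                            and mask[u, v, w] and not visited[u, v, w]
                            and bins[u, v, w] == level
                        ):
                            visited[u, v, w] = True
                            queue.append((u, v, w))
                M[level, size] += 1
    return M


def oracle_glszm_features(bins: np.ndarray, mask: np.ndarray, B: int) -> dict[str, float]:
    M = oracle_glszm_matrix(bins, mask, B)
    Ns = M.sum()
    Nv = int(mask.sum())
    G, S = M.shape
    out = {k: 0.0 for k in (
        "small_zone_emphasis", "large_zone_emphasis", "low_gray_level_emphasis",
        "high_gray_level_emphasis", "small_zone_low_gray_level_emphasis",
        "small_zone_high_gray_level_emphasis", "large_zone_low_gray_level_emphasis",
        "large_zone_high_gray_level_emphasis", "zone_size_entropy",
    )}
    for g in range(1, G):
        for s in range(1, S):
            m = M[g, s]
            if m == 0:
                continue
            out["small_zone_emphasis"] += m / s**2
            out["large_zone_emphasis"] += m * s**2
            out["low_gray_level_emphasis"] += m / g**2
            out["high_gray_level_emphasis"] += m * g**2
            out["small_zone_low_gray_level_emphasis"] += m / (g**2 * s**2)
            out["small_zone_high_gray_level_emphasis"] += m * g**2 / s**2
            out["large_zone_low_gray_level_emphasis"] += m * s**2 / g**2
            out["large_zone_high_gray_level_emphasis"] += m * g**2 * s**2
            out["zone_size_entropy"] -= m / Ns * math.log2(m / Ns)
    for k in out:
        if k != "zone_size_entropy":
            out[k] /= Ns
    mg = [M[g, :].sum() for g in range(G)]
    mz = [M[:, s].sum() for s in range(S)]
    out["gray_level_nonuniformity"] = sum(v**2 for v in mg) / Ns
    out["gray_level_nonuniformity_normalized"] = sum(v**2 for v in mg) / Ns**2
    out["zone_size_nonuniformity"] = sum(v**2 for v in mz) / Ns
    out["zone_size_nonuniformity_normalized"] = sum(v**2 for v in mz) / Ns**2
    out["zone_percentage"] = Ns / Nv
    return {f"glszm_{k}": v for k, v in out.items()}


def oracle_fusion_matrix(pet_bins, ct_bins, mask, B) -> np.ndarray:
    M = np.zeros((B, B))
    nx, ny, nz = pet_bins.shape
    for x in range(nx):
        for y in range(ny):
            for z in range(nz):
                if mask[x, y, z]:
                    M[pet_bins[x, y, z] - 1, ct_bins[x, y, z] - 1] += 1
    return M / M.sum()


def oracle_histogram_features(bins, mask, B, raw=None) -> dict[str, float]:
    vals = [int(v) for v in bins[mask]]
    N = len(vals)
    p = [vals.count(i) / N for i in range(1, B + 1)]
    mean = sum((i + 1) * pi for i, pi in enumerate(p))
    var = sum((i + 1 - mean) ** 2 * pi for i, pi in enumerate(p))
    skew = sum((i + 1 - mean) ** 3 * pi for i, pi in enumerate(p)) / var**1.5 if var > 0 else 0.0
    kurt = sum((i + 1 - mean) ** 4 * pi for i, pi in enumerate(p)) / var**2 - 3 if var > 0 else 0.0
    out = {
        "hist_mean": mean,
        "hist_variance": var,
        "hist_skewness": skew,
        "hist_kurtosis": kurt,
        "hist_uniformity": sum(pi**2 for pi in p),
        "hist_entropy": -sum(pi * math.log2(pi) for pi in p if pi > 0),
    }
    if raw is not None:
        inmask = raw[mask]
        out["intensity_range"] = float(inmask.max() - inmask.min())
    return out
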