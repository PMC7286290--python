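"""Haralick texture statistics from 3D gray-level co-occurrence matrices.

For each segment, intensities inside the segment are min–max quantized to
``n_gray_levels``; a symmetric GLCM is accumulated for each 3D offset
(default: the 13 unique direction vectors at distance 1, i.e. half of the
26-neighbourhood) and normalized, and the 13 classic Haralick statistics
are computed per offset and averaged.  Quantization is per segment, which
makes the features invariant to affine rescaling of the segment's
intensities.
"""

from __future__ import annotations

import numpy as np

HARALICK_NAMES = [
    "angular_second_moment",
    "contrast",
    "correlation",
    "variance",
    "inverse_difference_moment",
    "sum_average",
    "sum_variance",
    "sum_entropy",
    "entropy",
    "difference_variance",
    "difference_entropy",
    "info_measure_correlation_1",
    "info_measure_correlation_2",
]

#: the 13 unique 3D direction vectors at chessboard distance 1 (z, y, x)
OFFSETS_3D = [
    (0, 0, 1), (0, 1, 0), (1, 0, 0),
    (0, 1, 1), (0, 1, -1),
    (1, 0, 1), (1, 0, -1),
    (1, 1, 0), (1, -1, 0),
    (1, 1, 1), (1, 1, -1), (1, -1, 1), (1, -1, -1),
]


def quantize(values: np.ndarray, n_levels: int) -> np.ndarray:
    """Min–max quantize to integer levels 0..n_levels-1."""
    values = np.asarray(values, dtype=float)
    lo, hi = values.min(), values.max()
    if hi <= lo:
        return np.zeros(values.shape, dtype=np.int32)
    q = np.floor((values - lo) / (hi - lo) * n_levels).astype(np.int32)
    return np.clip(q, 0, n_levels - 1)


def glcm_3d(quantized: np.ndarray, mask: np.ndarray, offset, n_levels: int) -> np.ndarray:
    """Symmetric normalized GLCM for one (dz, dy, dx) offset.

    Only voxel pairs with both ends inside ``mask`` contribute.  Returns an
    ``(n_levels, n_levels)`` matrix summing to 1 (all-zero if the offset
    yields no valid pair).
    """
    dz, dy, dx = offset
    sl_a, sl_b = [], []
    for d, n in zip((dz, dy, dx), quantized.shape):
        if d >= 0:
            sl_a.append(slice(0, n - d))
            sl_b.append(slice(d, n))
        else:
            sl_a.append(slice(-d, n))
            sl_b.append(slice(0, n + d))
    a = quantized[tuple(sl_a)]
    b = quantized[tuple(sl_b)]
    ok = mask[tuple(sl_a)] & mask[tuple(sl_b)]
    if not ok.any():
        return np.zeros((n_levels, n_levels))
    pairs = a[ok].astype(np.int64) * n_levels + b[ok]
    counts = np.bincount(pairs, minlength=n_levels * n_levels).reshape(n_levels, n_levels)
    counts = counts + counts.T  # symmetric
    return counts / counts.sum()


def haralick_from_glcm(P: np.ndarray) -> np.ndarray:
    """The 13 Haralick statistics of one normalized GLCM."""
    L = P.shape[0]
    if P.sum() <= 0:
        return np.full(13, np.nan)
    i = np.arange(L, dtype=float)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = P.sum(axis=1)
    py = P.sum(axis=0)
    mu_x = (i * px).sum()
    mu_y = (i * py).sum()
    sd_x = np.sqrt(((i - mu_x) ** 2 * px).sum())
    sd_y = np.sqrt(((i - mu_y) ** 2 * py).sum())

    # distributions of i+j and |i-j|
    p_sum = np.zeros(2 * L - 1)
    np.add.at(p_sum, (ii + jj).astype(int).ravel(), P.ravel())
    p_diff = np.zeros(L)
    np.add.at(p_diff, np.abs(ii - jj).astype(int).ravel(), P.ravel())
    k_sum = np.arange(2 * L - 1, dtype=float)
    k_diff = np.arange(L, dtype=float)

    def ent(p):
        p = p[p > 0]
        return float(-(p * np.log2(p)).sum())

    asm = float((P**2).sum())
    contrast = float((k_diff**2 * p_diff).sum())
    corr = 0.0
    if sd_x > 0 and sd_y > 0:
        corr = float(((ii * jj * P).sum() - mu_x * mu_y) / (sd_x * sd_y))
    variance = float((((ii - mu_x) ** 2) * P).sum())
    idm = float((P / (1.0 + (ii - jj) ** 2)).sum())
    sum_avg = float((k_sum * p_sum).sum())
    sum_var = float(((k_sum - sum_avg) ** 2 * p_sum).sum())
    sum_ent = ent(p_sum)
    entropy = ent(P.ravel())
    diff_avg = float((k_diff * p_diff).sum())
    diff_var = float(((k_diff - diff_avg) ** 2 * p_diff).sum())
    diff_ent = ent(p_diff)

    # information measures of correlation
    hx, hy = ent(px), ent(py)
    pxy_outer = np.outer(px, py)
    nz = (P > 0) & (pxy_outer > 0)
    hxy1 = float(-(P[nz] * np.log2(pxy_outer[nz])).sum())
    nz2 = pxy_outer > 0
    hxy2 = float(-(pxy_outer[nz2] * np.log2(pxy_outer[nz2])).sum())
    denom = max(hx, hy)
    imc1 = (entropy - hxy1) / denom if denom > 0 else 0.0
    imc2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - entropy)))))

    return np.array([asm, contrast, corr, variance, idm, sum_avg, sum_var,
                     sum_ent, entropy, diff_var, diff_ent, imc1, imc2])


def haralick_features(
    intensity: np.ndarray,
    mask: np.ndarray,
    n_gray_levels: int = 32,
    offsets=None,
) -> np.ndarray:
    """13-vector of Haralick features for one segment.

    ``intensity`` and ``mask`` are matching 3D arrays (typically a bounding
    box crop).  Features are averaged over offsets; offsets producing no
    valid pair are skipped.
    """
    offsets = OFFSETS_3D if offsets is None else offsets
    mask = np.asarray(mask, bool)
    # quantize only inside the mask
    vals = np.zeros(mask.shape, dtype=np.int32)
    vals[mask] = quantize(np.asarray(intensity, dtype=float)[mask], n_gray_levels)
    feats = []
    for off in offsets:
        P = glcm_3d(vals, mask, off, n_gray_levels)
        if P.sum() > 0:
            feats.append(haralick_from_glcm(P))
    if not feats:
        return np.full(13, np.nan)
    return np.mean(feats, axis=0)
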