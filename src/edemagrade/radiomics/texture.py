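"""Gray-level texture-matrix families on a discretized ROI.

All families operate on a :class:`DiscretizedROI`: an integer array of
gray levels 1..Ng on the ROI bounding box, 0 outside the ROI.

* GLCM  — symmetric distance-1 co-occurrence over the 13 unique 3D
  directions; features computed per direction and averaged.
* GLRLM — run lengths along the same 13 directions, averaged.
* GLSZM — zone sizes of 26-connected equal-level components.
* GLDM  — dependence counts in the distance-1 26-neighborhood
  (dependence size = 1 + number of neighbors within ``alpha`` levels).
* NGTDM — distance-1 neighborhood gray-tone differences.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .registry import (
    GLCM_FEATURES,
    GLDM_FEATURES,
    GLRLM_FEATURES,
    GLSZM_FEATURES,
    NGTDM_FEATURES,
)
from .roi import DiscretizedROI

__all__ = [
    "DIRECTIONS_13",
    "glcm_matrix",
    "glcm_features",
    "glrlm_matrices",
    "glrlm_features",
    "glszm_matrix",
    "glszm_features",
    "gldm_matrix",
    "gldm_features",
    "ngtdm_table",
    "ngtdm_features",
    "NGTDM_COARSENESS_SENTINEL",
]

#: The 13 unique 3D directions (canonical form: first nonzero step +1).
DIRECTIONS_13: tuple[tuple[int, int, int], ...] = (
    (0, 0, 1), (0, 1, 0), (1, 0, 0),
    (0, 1, 1), (0, 1, -1), (1, 0, 1), (1, 0, -1), (1, 1, 0), (1, -1, 0),
    (1, 1, 1), (1, 1, -1), (1, -1, 1), (1, -1, -1),
)

#: All 26 neighbor offsets (distance-1 Chebyshev neighborhood).
OFFSETS_26: tuple[tuple[int, int, int], ...] = tuple(
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) != (0, 0, 0)
)

NGTDM_COARSENESS_SENTINEL = 1e6



def _shifted_views(arr: np.ndarray, offset: tuple[int, int, int]):
    """Overlapping views (base, shifted) of ``arr`` for a voxel offset."""
    slices_a, slices_b = [], []
    for d, size in zip(offset, arr.shape):
        if d >= 0:
            slices_a.append(slice(0, size - d))
            slices_b.append(slice(d, size))
        else:
            slices_a.append(slice(-d, size))
            slices_b.append(slice(0, size + d))
    return arr[tuple(slices_a)], arr[tuple(slices_b)]


# ---------------------------------------------------------------------------
# GLCM
# ---------------------------------------------------------------------------


def glcm_matrix(d: DiscretizedROI, direction: tuple[int, int, int]) -> np.ndarray:
    """Symmetric co-occurrence counts for one direction (Ng x Ng)."""
    ng = d.Ng
    a, b = _shifted_views(d.levels, direction)
    valid = (a > 0) & (b > 0)
    i = a[valid] - 1
    j = b[valid] - 1
    counts = np.bincount(i * ng + j, minlength=ng * ng).reshape(ng, ng).astype(np.float64)
    return counts + counts.T


def _glcm_features_one(P: np.ndarray) -> dict[str, float]:
    ng = P.shape[0]
    total = P.sum()
    if total == 0:
        # no voxel pairs along this direction; contributes neutral zeros
        return {name: 0.0 for name in GLCM_FEATURES}
    p = P / total
    i = np.arange(1, ng + 1, dtype=np.float64)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = p.sum(axis=1)
    mu = float((i * px).sum())  # symmetric: mu_x == mu_y
    sigma2 = float(((i - mu) ** 2 * px).sum())

    diff = np.abs(ii - jj)
    k_diff = np.arange(0, ng, dtype=np.float64)
    p_diff = np.array([p[diff == k].sum() for k in k_diff])
    k_sum = np.arange(2, 2 * ng + 1, dtype=np.float64)
    p_sum = np.array([p[(ii + jj) == k].sum() for k in k_sum])

    da = float((k_diff * p_diff).sum())
    nz_d = p_diff > 0
    nz_s = p_sum > 0
    nz_p = p > 0

    hxy = float(-(p[nz_p] * np.log2(p[nz_p])).sum())
    px_py = np.outer(px, px)
    log_pxpy = np.zeros_like(px_py)
    pos = px_py > 0
    log_pxpy[pos] = np.log2(px_py[pos])
    hxy1 = float(-(p * log_pxpy).sum())
    hxy2 = float(-(px_py * log_pxpy).sum())
    hx = float(-(px[px > 0] * np.log2(px[px > 0])).sum())
    imc1 = (hxy - hxy1) / hx if hx > 0 else 0.0
    arg = -2.0 * (hxy2 - hxy)
    imc2 = float(np.sqrt(1.0 - np.exp(arg))) if arg < 0 else 0.0

    corr = float(((ii - mu) * (jj - mu) * p).sum() / sigma2) if sigma2 > 0 else 1.0

    # MCC: sqrt of the second-largest eigenvalue of
    # Q(i,j) = sum_k p(i,k) p(j,k) / (px(i) py(k))
    if ng > 1 and (px > 0).sum() > 1:
        w = np.zeros_like(px)
        w[px > 0] = 1.0 / px[px > 0]
        q = (w[:, None] * p) @ (p * w[None, :]).T
        eig = np.sort(np.linalg.eigvals(q).real)
        mcc = float(np.sqrt(max(eig[-2], 0.0)))
    else:
        mcc = 1.0

    inv_var_mask = diff > 0
    out = {
        "Autocorrelation": float((ii * jj * p).sum()),
        "JointAverage": mu,
        "ClusterProminence": float(((ii + jj - 2 * mu) ** 4 * p).sum()),
        "ClusterShade": float(((ii + jj - 2 * mu) ** 3 * p).sum()),
        "ClusterTendency": float(((ii + jj - 2 * mu) ** 2 * p).sum()),
        "Contrast": float(((ii - jj) ** 2 * p).sum()),
        "Correlation": corr,
        "DifferenceAverage": da,
        "DifferenceEntropy": float(-(p_diff[nz_d] * np.log2(p_diff[nz_d])).sum()),
        "DifferenceVariance": float(((k_diff - da) ** 2 * p_diff).sum()),
        "JointEnergy": float((p**2).sum()),
        "JointEntropy": hxy,
        "Imc1": float(imc1),
        "Imc2": imc2,
        "Idm": float((p / (1.0 + (ii - jj) ** 2)).sum()),
        "Idmn": float((p / (1.0 + ((ii - jj) / ng) ** 2)).sum()),
        "Id": float((p / (1.0 + diff)).sum()),
        "Idn": float((p / (1.0 + diff / ng)).sum()),
        "InverseVariance": float((p[inv_var_mask] / diff[inv_var_mask] ** 2).sum()),
        "MaximumProbability": float(p.max()),
        "SumAverage": float((k_sum * p_sum).sum()),
        "SumEntropy": float(-(p_sum[nz_s] * np.log2(p_sum[nz_s])).sum()),
        "SumSquares": float(((ii - mu) ** 2 * p).sum()),
        "MCC": mcc,
    }
    return out


def glcm_features(d: DiscretizedROI) -> dict[str, float]:
    """24 GLCM features, averaged over the 13 directions."""
    acc = {name: 0.0 for name in GLCM_FEATURES}
    n_used = 0
    for direction in DIRECTIONS_13:
        P = glcm_matrix(d, direction)
        if P.sum() == 0:
            continue
        feats = _glcm_features_one(P)
        for name in GLCM_FEATURES:
            acc[name] += feats[name]
        n_used += 1
    if n_used == 0:
        # single isolated voxel: no co-occurring pairs in any direction
        base = {name: 0.0 for name in GLCM_FEATURES}
        base["MaximumProbability"] = 1.0
        base["Correlation"] = 1.0
        base["MCC"] = 1.0
        return base
    return {name: acc[name] / n_used for name in GLCM_FEATURES}


# ---------------------------------------------------------------------------
# GLRLM
# ---------------------------------------------------------------------------


def _runs_along(levels: np.ndarray, direction: tuple[int, int, int]):
    """(gray level, run length) pairs of maximal runs along a direction."""
    shape = levels.shape
    idx = np.indices(shape).reshape(3, -1)
    d = np.asarray(direction)
    first_axis = int(np.nonzero(d)[0][0])
    t = idx[first_axis] * d[first_axis]  # d[first_axis] == +1 canonically
    keys = [idx[a] - t * d[a] for a in range(3)]
    order = np.lexsort((t, keys[2], keys[1], keys[0]))
    vals = levels.reshape(-1)[order]
    k0, k1, k2 = (k[order] for k in keys)
    new_line = np.ones(vals.size, dtype=bool)
    if vals.size > 1:
        new_line[1:] = (np.diff(k0) != 0) | (np.diff(k1) != 0) | (np.diff(k2) != 0)
    new_run = new_line.copy()
    if vals.size > 1:
        new_run[1:] |= np.diff(vals) != 0
    run_ids = np.cumsum(new_run) - 1
    run_lengths = np.bincount(run_ids)
    run_levels = vals[new_run]
    keep = run_levels > 0
    return run_levels[keep], run_lengths[keep]


def glrlm_matrices(d: DiscretizedROI) -> list[np.ndarray]:
    """Per-direction run-length matrices (Ng x max run length)."""
    mats = []
    for direction in DIRECTIONS_13:
        levels_, lengths_ = _runs_along(d.levels, direction)
        if levels_.size == 0:
            mats.append(np.zeros((d.Ng, 1)))
            continue
        max_len = int(lengths_.max())
        R = np.zeros((d.Ng, max_len))
        np.add.at(R, (levels_ - 1, lengths_ - 1), 1.0)
        mats.append(R)
    return mats


def _rlm_features_one(R: np.ndarray, n_voxels: int) -> dict[str, float]:
    nr = R.sum()
    if nr == 0:
        return {name: 0.0 for name in GLRLM_FEATURES}
    i = np.arange(1, R.shape[0] + 1, dtype=np.float64)
    j = np.arange(1, R.shape[1] + 1, dtype=np.float64)
    ii, jj = np.meshgrid(i, j, indexing="ij")
    p = R / nr
    mu_i = float((ii * p).sum())
    mu_j = float((jj * p).sum())
    ri = R.sum(axis=1)
    rj = R.sum(axis=0)
    nz = p > 0
    out = {
        "ShortRunEmphasis": float((R / jj**2).sum() / nr),
        "LongRunEmphasis": float((R * jj**2).sum() / nr),
        "GrayLevelNonUniformity": float((ri**2).sum() / nr),
        "GrayLevelNonUniformityNormalized": float((ri**2).sum() / nr**2),
        "RunLengthNonUniformity": float((rj**2).sum() / nr),
        "RunLengthNonUniformityNormalized": float((rj**2).sum() / nr**2),
        "RunPercentage": float(nr / n_voxels),
        "GrayLevelVariance": float(((ii - mu_i) ** 2 * p).sum()),
        "RunVariance": float(((jj - mu_j) ** 2 * p).sum()),
        "RunEntropy": float(-(p[nz] * np.log2(p[nz])).sum()),
        "LowGrayLevelRunEmphasis": float((R / ii**2).sum() / nr),
        "HighGrayLevelRunEmphasis": float((R * ii**2).sum() / nr),
        "ShortRunLowGrayLevelEmphasis": float((R / (ii**2 * jj**2)).sum() / nr),
        "ShortRunHighGrayLevelEmphasis": float((R * ii**2 / jj**2).sum() / nr),
        "LongRunLowGrayLevelEmphasis": float((R * jj**2 / ii**2).sum() / nr),
        "LongRunHighGrayLevelEmphasis": float((R * ii**2 * jj**2).sum() / nr),
    }
    return out


def glrlm_features(d: DiscretizedROI) -> dict[str, float]:
    """16 GLRLM features, averaged over the 13 directions."""
    n_vox = d.n_voxels
    acc = {name: 0.0 for name in GLRLM_FEATURES}
    mats = glrlm_matrices(d)
    for R in mats:
        feats = _rlm_features_one(R, n_vox)
        for name in GLRLM_FEATURES:
            acc[name] += feats[name]
    return {name: acc[name] / len(mats) for name in GLRLM_FEATURES}


# ---------------------------------------------------------------------------
# GLSZM
# ---------------------------------------------------------------------------

_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


def glszm_matrix(d: DiscretizedROI) -> np.ndarray:
    """Size-zone counts (Ng x max zone size), 26-connectivity."""
    sizes_per_level: list[tuple[int, np.ndarray]] = []
    max_size = 1
    for g in range(1, d.Ng + 1):
        labelled, n_zones = ndimage.label(d.levels == g, structure=_STRUCT_26)
        if n_zones == 0:
            continue
        sizes = np.bincount(labelled.ravel())[1:]
        sizes_per_level.append((g, sizes))
        max_size = max(max_size, int(sizes.max()))
    S = np.zeros((d.Ng, max_size))
    for g, sizes in sizes_per_level:
        np.add.at(S, (np.full(sizes.size, g - 1), sizes - 1), 1.0)
    return S


def glszm_features(d: DiscretizedROI) -> dict[str, float]:
    """16 GLSZM features from the 26-connected size-zone matrix."""
    S = glszm_matrix(d)
    nz_total = S.sum()
    n_vox = d.n_voxels
    if nz_total == 0:
        return {name: 0.0 for name in GLSZM_FEATURES}
    i = np.arange(1, S.shape[0] + 1, dtype=np.float64)
    j = np.arange(1, S.shape[1] + 1, dtype=np.float64)
    ii, jj = np.meshgrid(i, j, indexing="ij")
    p = S / nz_total
    mu_i = float((ii * p).sum())
    mu_j = float((jj * p).sum())
    si = S.sum(axis=1)
    sj = S.sum(axis=0)
    nz = p > 0
    out = {
        "SmallAreaEmphasis": float((S / jj**2).sum() / nz_total),
        "LargeAreaEmphasis": float((S * jj**2).sum() / nz_total),
        "GrayLevelNonUniformity": float((si**2).sum() / nz_total),
        "GrayLevelNonUniformityNormalized": float((si**2).sum() / nz_total**2),
        "SizeZoneNonUniformity": float((sj**2).sum() / nz_total),
        "SizeZoneNonUniformityNormalized": float((sj**2).sum() / nz_total**2),
        "ZonePercentage": float(nz_total / n_vox),
        "GrayLevelVariance": float(((ii - mu_i) ** 2 * p).sum()),
        "ZoneVariance": float(((jj - mu_j) ** 2 * p).sum()),
        "ZoneEntropy": float(-(p[nz] * np.log2(p[nz])).sum()),
        "LowGrayLevelZoneEmphasis": float((S / ii**2).sum() / nz_total),
        "HighGrayLevelZoneEmphasis": float((S * ii**2).sum() / nz_total),
        "SmallAreaLowGrayLevelEmphasis": float((S / (ii**2 * jj**2)).sum() / nz_total),
        "SmallAreaHighGrayLevelEmphasis": float((S * ii**2 / jj**2).sum() / nz_total),
        "LargeAreaLowGrayLevelEmphasis": float((S * jj**2 / ii**2).sum() / nz_total),
        "LargeAreaHighGrayLevelEmphasis": float((S * ii**2 * jj**2).sum() / nz_total),
    }
    return {name: out[name] for name in GLSZM_FEATURES}


# ---------------------------------------------------------------------------
# GLDM
# ---------------------------------------------------------------------------


def gldm_matrix(d: DiscretizedROI, alpha: int = 0) -> np.ndarray:
    """Dependence counts: D[i-1, k-1] = #voxels of level i with
    dependence size k, where k = 1 + #26-neighbors within ``alpha``
    levels of the center (the center counts itself)."""
    lev = d.levels
    dep = np.zeros(lev.shape, dtype=np.int64)
    for off in OFFSETS_26:
        a, b = _shifted_views(lev, off)
        contrib = (a > 0) & (b > 0) & (np.abs(a - b) <= alpha)
        # accumulate into the *base* view positions
        slices_a = []
        for dd, size in zip(off, lev.shape):
            slices_a.append(slice(0, size - dd) if dd >= 0 else slice(-dd, size))
        dep[tuple(slices_a)] += contrib
    inroi = lev > 0
    sizes = dep[inroi] + 1
    levels = lev[inroi]
    D = np.zeros((d.Ng, int(sizes.max())))
    np.add.at(D, (levels - 1, sizes - 1), 1.0)
    return D


def gldm_features(d: DiscretizedROI, alpha: int = 0) -> dict[str, float]:
    """14 GLDM features from the distance-1 dependence matrix."""
    D = gldm_matrix(d, alpha)
    nz_total = D.sum()
    i = np.arange(1, D.shape[0] + 1, dtype=np.float64)
    j = np.arange(1, D.shape[1] + 1, dtype=np.float64)
    ii, jj = np.meshgrid(i, j, indexing="ij")
    p = D / nz_total
    mu_i = float((ii * p).sum())
    mu_j = float((jj * p).sum())
    di = D.sum(axis=1)
    dj = D.sum(axis=0)
    nz = p > 0
    out = {
        "SmallDependenceEmphasis": float((D / jj**2).sum() / nz_total),
        "LargeDependenceEmphasis": float((D * jj**2).sum() / nz_total),
        "GrayLevelNonUniformity": float((di**2).sum() / nz_total),
        "DependenceNonUniformity": float((dj**2).sum() / nz_total),
        "DependenceNonUniformityNormalized": float((dj**2).sum() / nz_total**2),
        "GrayLevelVariance": float(((ii - mu_i) ** 2 * p).sum()),
        "DependenceVariance": float(((jj - mu_j) ** 2 * p).sum()),
        "DependenceEntropy": float(-(p[nz] * np.log2(p[nz])).sum()),
        "LowGrayLevelEmphasis": float((D / ii**2).sum() / nz_total),
        "HighGrayLevelEmphasis": float((D * ii**2).sum() / nz_total),
        "SmallDependenceLowGrayLevelEmphasis": float((D / (ii**2 * jj**2)).sum() / nz_total),
        "SmallDependenceHighGrayLevelEmphasis": float((D * ii**2 / jj**2).sum() / nz_total),
        "LargeDependenceLowGrayLevelEmphasis": float((D * jj**2 / ii**2).sum() / nz_total),
        "LargeDependenceHighGrayLevelEmphasis": float((D * ii**2 * jj**2).sum() / nz_total),
    }
    return {name: out[name] for name in GLDM_FEATURES}


# ---------------------------------------------------------------------------
# NGTDM
# ---------------------------------------------------------------------------


def ngtdm_table(d: DiscretizedROI) -> tuple[np.ndarray, np.ndarray]:
    """(n_i, s_i) per gray level i = 1..Ng.

    s_i sums |i - mean(valid 26-neighbors)| over the ROI voxels of level
    i; voxels with no in-ROI neighbor contribute zero.
    """
    lev = d.levels.astype(np.float64)
    inroi = d.levels > 0
    kernel = np.ones((3, 3, 3))
    kernel[1, 1, 1] = 0.0
    neigh_sum = ndimage.correlate(lev * inroi, kernel, mode="constant", cval=0.0)
    neigh_cnt = ndimage.correlate(inroi.astype(np.float64), kernel, mode="constant", cval=0.0)
    has_neigh = inroi & (neigh_cnt > 0)
    diff = np.zeros(lev.shape)
    diff[has_neigh] = np.abs(
        lev[has_neigh] - neigh_sum[has_neigh] / neigh_cnt[has_neigh]
    )
    n_i = np.bincount(d.levels[inroi] - 1, minlength=d.Ng).astype(np.float64)
    s_i = np.bincount(d.levels[inroi] - 1, weights=diff[inroi], minlength=d.Ng)
    return n_i, s_i


def ngtdm_features(d: DiscretizedROI) -> dict[str, float]:
    """The 5 NGTDM features; Coarseness of a uniform ROI hits its
    documented large-value sentinel (division by zero otherwise)."""
    n_i, s_i = ngtdm_table(d)
    n_total = n_i.sum()
    p_i = n_i / n_total
    present = p_i > 0
    ngp = int(present.sum())
    i = np.arange(1, d.Ng + 1, dtype=np.float64)

    coarse_denom = float((p_i * s_i).sum())
    coarseness = 1.0 / coarse_denom if coarse_denom > 0 else NGTDM_COARSENESS_SENTINEL

    if ngp > 1:
        pi_v = p_i[present]
        i_v = i[present]
        si_v = s_i[present]
        diff2 = (i_v[:, None] - i_v[None, :]) ** 2
        pp = pi_v[:, None] * pi_v[None, :]
        contrast = float(
            (pp * diff2).sum() / (ngp * (ngp - 1)) * (s_i.sum() / n_total)
        )
        busy_denom = float(np.abs(i_v[:, None] * pi_v[:, None] - i_v[None, :] * pi_v[None, :]).sum())
        busyness = float((pi_v * si_v).sum() / busy_denom) if busy_denom > 0 else 0.0
        psps = pi_v[:, None] * si_v[:, None] + pi_v[None, :] * si_v[None, :]
        complexity = float(
            (np.abs(i_v[:, None] - i_v[None, :]) * psps / (pi_v[:, None] + pi_v[None, :])).sum()
            / n_total
        )
        s_total = float(s_i.sum())
        strength = (
            float(((pi_v[:, None] + pi_v[None, :]) * diff2).sum() / s_total)
            if s_total > 0
            else 0.0
        )
    else:
        contrast = 0.0
        busyness = 0.0
        complexity = 0.0
        strength = 0.0

    out = {
        "Coarseness": float(coarseness),
        "Contrast": contrast,
        "Busyness": busyness,
        "Complexity": complexity,
        "Strength": strength,
    }
    return {name: out[name] for name in NGTDM_FEATURES}
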