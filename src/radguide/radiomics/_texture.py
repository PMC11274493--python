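"""Texture matrices and their features (GLCM, GLRLM, GLSZM, GLDM, NGTDM).

Conventions:

* 3D neighborhoods use the 13 unique direction offsets at Chebyshev
  distance 1 (the symmetric half of the 26-neighborhood);
* GLCM is accumulated symmetrically (each ordered pair counted both ways),
  normalized per direction, features averaged over directions;
* GLRLM runs are counted per direction, out-of-ROI voxels break runs,
  features averaged over directions;
* GLSZM zones are 26-connected components of equal level (no direction);
* GLDM dependence is the number of 26-neighbors within ``alpha`` of the
  center level; matrix columns are indexed by dependence + 1;
* NGTDM uses the mean over valid in-ROI 26-neighbors.

Degenerate single-level ROIs are mapped to fixed values (GLCM correlation
and MCC = 1, NGTDM coarseness capped at 1e6, 0/0 = 0 elsewhere) so feature
vectors are always NaN-free.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from radguide.radiomics._discretize import DiscretizedROI

#: the 13 unique 3D direction offsets (first nonzero component positive)
ANGLES: tuple[tuple[int, int, int], ...] = tuple(
    d for d in (
        (dx, dy, dz)
        for dx in (-1, 0, 1) for dy in (-1, 0, 1) for dz in (-1, 0, 1)
        if (dx, dy, dz) != (0, 0, 0)
    )
    if next(c for c in d if c != 0) > 0
)

_STRUCT26 = np.ones((3, 3, 3), dtype=bool)

_COARSENESS_CAP = 1e6


def _offset_slices(shape, d):
    """Aligned slice pairs (sa, sb) so grid[sa] and grid[sb] are (v, v+d)."""
    sa, sb = [], []
    for s, step in zip(shape, d):
        if step >= 0:
            sa.append(slice(0, s - step))
            sb.append(slice(step, s))
        else:
            sa.append(slice(-step, s))
            sb.append(slice(0, s + step))
    return tuple(sa), tuple(sb)


def _entropy(p: np.ndarray) -> float:
    nz = p[p > 0]
    return float(-(nz * np.log2(nz)).sum())


# ---------------------------------------------------------------------------
# GLCM
# ---------------------------------------------------------------------------

def glcm_matrix(droi: DiscretizedROI, distance: int = 1) -> list[np.ndarray]:
    """Symmetric co-occurrence count matrices, one per direction."""
    grid, ng = droi.grid, droi.ng
    mats = []
    for d in ANGLES:
        dd = tuple(distance * c for c in d)
        sa, sb = _offset_slices(grid.shape, dd)
        a, b = grid[sa].ravel(), grid[sb].ravel()
        valid = (a > 0) & (b > 0)
        a, b = a[valid] - 1, b[valid] - 1
        mat = np.zeros((ng, ng), dtype=np.float64)
        np.add.at(mat, (a, b), 1.0)
        np.add.at(mat, (b, a), 1.0)
        mats.append(mat)
    return mats


def _glcm_features_single(counts: np.ndarray) -> dict[str, float]:
    ng = counts.shape[0]
    total = counts.sum()
    if total == 0:
        # no voxel pairs in this direction (e.g. single-voxel ROI)
        p = np.zeros_like(counts)
    else:
        p = counts / total
    i = np.arange(1, ng + 1, dtype=np.float64)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px, py = p.sum(1), p.sum(0)
    mu_x, mu_y = float((i * px).sum()), float((i * py).sum())
    var_x = float(((i - mu_x) ** 2 * px).sum())
    var_y = float(((i - mu_y) ** 2 * py).sum())

    # diagonal (difference) and cross-diagonal (sum) distributions
    k_diff = np.arange(ng, dtype=np.float64)             # |i-j| = 0..Ng-1
    k_sum = np.arange(2, 2 * ng + 1, dtype=np.float64)   # i+j = 2..2Ng
    diff_idx = np.abs(ii - jj).astype(np.int64).ravel()
    sum_idx = (ii + jj).astype(np.int64).ravel() - 2
    p_diff = np.bincount(diff_idx, weights=p.ravel(), minlength=ng)
    p_sum = np.bincount(sum_idx, weights=p.ravel(), minlength=2 * ng - 1)

    autocorr = float((ii * jj * p).sum())
    contrast = float(((ii - jj) ** 2 * p).sum())
    if var_x > 0 and var_y > 0:
        correlation = (autocorr - mu_x * mu_y) / np.sqrt(var_x * var_y)
    else:
        correlation = 1.0
    diff_avg = float((k_diff * p_diff).sum())
    diff_var = float(((k_diff - diff_avg) ** 2 * p_diff).sum())
    hxy = _entropy(p)
    hx, hy = _entropy(px), _entropy(py)
    outer = px[:, None] * py[None, :]
    mask = (p > 0) & (outer > 0)
    hxy1 = float(-(p[mask] * np.log2(outer[mask])).sum())
    m2 = outer > 0
    hxy2 = float(-(outer[m2] * np.log2(outer[m2])).sum())
    imc1 = (hxy - hxy1) / max(hx, hy) if max(hx, hy) > 0 else 0.0
    imc2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - hxy)))))

    # MCC on levels actually present
    present = px > 0
    if present.sum() <= 1 or total == 0:
        mcc = 1.0
    else:
        sub = p[np.ix_(present, present)]
        sx, sy = px[present], py[present]
        q = (sub / sx[:, None]) @ (sub / sy[None, :]).T
        eig = np.sort(np.real(np.linalg.eigvals(q)))[::-1]
        mcc = float(np.sqrt(np.clip(eig[1] if len(eig) > 1 else 1.0, 0.0, 1.0)))

    cm = ii + jj - mu_x - mu_y
    inv_var = float((p_diff[1:] / k_diff[1:] ** 2).sum())
    return {
        "Autocorrelation": autocorr,
        "JointAverage": mu_x,
        "ClusterProminence": float((cm ** 4 * p).sum()),
        "ClusterShade": float((cm ** 3 * p).sum()),
        "ClusterTendency": float((cm ** 2 * p).sum()),
        "Contrast": contrast,
        "Correlation": float(correlation),
        "DifferenceAverage": diff_avg,
        "DifferenceEntropy": _entropy(p_diff),
        "DifferenceVariance": diff_var,
        "Id": float((p_diff / (1.0 + k_diff)).sum()),
        "Idm": float((p_diff / (1.0 + k_diff ** 2)).sum()),
        "Idmn": float((p_diff / (1.0 + (k_diff / ng) ** 2)).sum()),
        "Idn": float((p_diff / (1.0 + k_diff / ng)).sum()),
        "Imc1": float(imc1),
        "Imc2": imc2,
        "InverseVariance": inv_var,
        "JointEnergy": float((p ** 2).sum()),
        "JointEntropy": hxy,
        "MCC": mcc,
        "MaximumProbability": float(p.max()) if total else 0.0,
        "SumAverage": float((k_sum * p_sum).sum()),
        "SumEntropy": _entropy(p_sum),
        "SumSquares": float(((ii - mu_x) ** 2 * p).sum()),
    }


def _xlog2x_sum(p: np.ndarray, axes) -> np.ndarray:
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(p > 0, p * np.log2(np.where(p > 0, p, 1.0)), 0.0)
    return -t.sum(axis=axes)


def glcm_features(matrices: list[np.ndarray]) -> dict[str, float]:
    """Per-direction features averaged over directions with nonzero pairs.

    Computation is batched over the direction axis for speed; the result is
    identical to evaluating :func:`_glcm_features_single` per direction.
    """
    nonzero = [m for m in matrices if m.sum() > 0]
    if not nonzero:
        return _glcm_features_single(matrices[0])
    counts = np.stack(nonzero)
    nd, ng, _ = counts.shape
    p = counts / counts.sum((1, 2), keepdims=True)
    i = np.arange(1, ng + 1, dtype=np.float64)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px, py = p.sum(2), p.sum(1)
    mu_x, mu_y = (i * px).sum(1), (i * py).sum(1)
    var_x = ((i[None, :] - mu_x[:, None]) ** 2 * px).sum(1)
    var_y = ((i[None, :] - mu_y[:, None]) ** 2 * py).sum(1)

    k_diff = np.arange(ng, dtype=np.float64)
    k_sum = np.arange(2, 2 * ng + 1, dtype=np.float64)
    diff_idx = np.abs(ii - jj).astype(np.int64).ravel()
    sum_idx = (ii + jj).astype(np.int64).ravel() - 2
    m_diff = np.zeros((ng * ng, ng))
    m_diff[np.arange(ng * ng), diff_idx] = 1.0
    m_sum = np.zeros((ng * ng, 2 * ng - 1))
    m_sum[np.arange(ng * ng), sum_idx] = 1.0
    flat = p.reshape(nd, -1)
    p_diff = flat @ m_diff
    p_sum = flat @ m_sum

    autocorr = (ii * jj * p).sum((1, 2))
    contrast = ((ii - jj) ** 2 * p).sum((1, 2))
    ok = (var_x > 0) & (var_y > 0)
    correlation = np.where(
        ok, (autocorr - mu_x * mu_y) / np.sqrt(np.where(ok, var_x * var_y, 1.0)), 1.0
    )
    diff_avg = (k_diff * p_diff).sum(1)
    diff_var = ((k_diff[None, :] - diff_avg[:, None]) ** 2 * p_diff).sum(1)
    hxy = _xlog2x_sum(p, (1, 2))
    hx, hy = _xlog2x_sum(px, 1), _xlog2x_sum(py, 1)
    outer = px[:, :, None] * py[:, None, :]
    log_outer = np.where(outer > 0, np.log2(np.where(outer > 0, outer, 1.0)), 0.0)
    hxy1 = -(np.where(p > 0, p * log_outer, 0.0)).sum((1, 2))
    hxy2 = -(outer * log_outer).sum((1, 2))
    denom = np.maximum(hx, hy)
    imc1 = np.where(denom > 0, (hxy - hxy1) / np.where(denom > 0, denom, 1.0), 0.0)
    imc2 = np.sqrt(np.clip(1.0 - np.exp(-2.0 * (hxy2 - hxy)), 0.0, None))

    mcc = np.empty(nd)
    for di in range(nd):
        present = px[di] > 0
        if present.sum() <= 1:
            mcc[di] = 1.0
            continue
        sub = p[di][np.ix_(present, present)]
        sx, sy = px[di][present], py[di][present]
        q = (sub / sx[:, None]) @ (sub / sy[None, :]).T
        eig = np.sort(np.real(np.linalg.eigvals(q)))[::-1]
        mcc[di] = np.sqrt(np.clip(eig[1], 0.0, 1.0))

    cm = ii[None] + jj[None] - mu_x[:, None, None] - mu_y[:, None, None]
    with np.errstate(divide="ignore"):
        inv_k2 = np.where(k_diff > 0, 1.0 / np.where(k_diff > 0, k_diff, 1.0) ** 2, 0.0)
    feats = {
        "Autocorrelation": autocorr,
        "JointAverage": mu_x,
        "ClusterProminence": (cm ** 4 * p).sum((1, 2)),
        "ClusterShade": (cm ** 3 * p).sum((1, 2)),
        "ClusterTendency": (cm ** 2 * p).sum((1, 2)),
        "Contrast": contrast,
        "Correlation": correlation,
        "DifferenceAverage": diff_avg,
        "DifferenceEntropy": _xlog2x_sum(p_diff, 1),
        "DifferenceVariance": diff_var,
        "Id": (p_diff / (1.0 + k_diff)).sum(1),
        "Idm": (p_diff / (1.0 + k_diff ** 2)).sum(1),
        "Idmn": (p_diff / (1.0 + (k_diff / ng) ** 2)).sum(1),
        "Idn": (p_diff / (1.0 + k_diff / ng)).sum(1),
        "Imc1": imc1,
        "Imc2": imc2,
        "InverseVariance": (p_diff * inv_k2).sum(1),
        "JointEnergy": (p ** 2).sum((1, 2)),
        "JointEntropy": hxy,
        "MCC": mcc,
        "MaximumProbability": p.max((1, 2)),
        "SumAverage": (k_sum * p_sum).sum(1),
        "SumEntropy": _xlog2x_sum(p_sum, 1),
        "SumSquares": (((ii[None] - mu_x[:, None, None]) ** 2) * p).sum((1, 2)),
    }
    return {k: float(np.mean(v)) for k, v in feats.items()}


# ---------------------------------------------------------------------------
# GLRLM
# ---------------------------------------------------------------------------

def _runs_one_direction(grid: np.ndarray, d: tuple[int, int, int]) -> tuple[np.ndarray, np.ndarray]:
    """(levels, lengths) of all maximal runs along direction d (level > 0)."""
    shape = grid.shape
    idx = np.indices(shape)
    outside_prev = np.zeros(shape, dtype=bool)
    for ax in range(3):
        prev = idx[ax] - d[ax]
        outside_prev |= (prev < 0) | (prev >= shape[ax])
    starts = np.argwhere(outside_prev)
    if len(starts) == 0:
        return np.empty(0, np.int64), np.empty(0, np.int64)
    k_max = max(shape)
    steps = np.arange(k_max)
    pos = starts[:, None, :] + steps[None, :, None] * np.asarray(d)[None, None, :]
    valid = np.all((pos >= 0) & (pos < np.asarray(shape)), axis=2)
    pc = np.clip(pos, 0, np.asarray(shape) - 1)
    lines = np.where(valid, grid[pc[..., 0], pc[..., 1], pc[..., 2]], 0)
    # flatten with a separator column so runs never span lines
    seq = np.concatenate(
        [lines, np.zeros((lines.shape[0], 1), dtype=lines.dtype)], axis=1
    ).ravel()
    change = np.flatnonzero(np.diff(seq)) + 1
    bounds = np.concatenate([[0], change, [seq.size]])
    lengths = np.diff(bounds)
    values = seq[bounds[:-1]]
    keep = values > 0
    return values[keep], lengths[keep]


def glrlm_matrix(droi: DiscretizedROI) -> list[np.ndarray]:
    """Run-length count matrices R(level, run length), one per direction."""
    mats = []
    max_len = max(droi.grid.shape)
    for d in ANGLES:
        levels, lengths = _runs_one_direction(droi.grid, d)
        mat = np.zeros((droi.ng, max_len), dtype=np.float64)
        np.add.at(mat, (levels - 1, lengths - 1), 1.0)
        mats.append(mat)
    return mats


def _weighted_moments(p_i: np.ndarray, axis_vals: np.ndarray) -> tuple[float, float]:
    mu = float((axis_vals * p_i).sum())
    var = float(((axis_vals - mu) ** 2 * p_i).sum())
    return mu, var


def _rlm_szm_features(mat: np.ndarray, n_voxels: int, prefix: str) -> dict[str, float]:
    """Shared run-length / size-zone feature formulas.

    ``prefix`` chooses the naming family: "Run"/"Zone" style differences are
    handled by the callers; here we compute on matrix counts with rows =
    gray level (1..Ng) and columns = run length or zone size (1..).
    """
    ns = mat.sum()
    i = np.arange(1, mat.shape[0] + 1, dtype=np.float64)
    j = np.arange(1, mat.shape[1] + 1, dtype=np.float64)
    ii, jj = np.meshgrid(i, j, indexing="ij")
    if ns == 0:
        ns = 1.0  # degenerate; all counts zero => all features zero
    p = mat / ns
    row = mat.sum(1)
    col = mat.sum(0)
    p_i = row / ns
    p_j = col / ns
    mu_i, var_i = _weighted_moments(p_i, i)
    mu_j, var_j = _weighted_moments(p_j, j)
    return {
        "SE": float(((mat / jj ** 2).sum()) / ns),
        "LE": float(((mat * jj ** 2).sum()) / ns),
        "GLN": float((row ** 2).sum() / ns),
        "GLNN": float((row ** 2).sum() / ns ** 2),
        "N": float((col ** 2).sum() / ns),
        "NN": float((col ** 2).sum() / ns ** 2),
        "Perc": float(ns / n_voxels),
        "GLV": var_i,
        "V": var_j,
        "Entropy": _entropy(p),
        "LGLE": float(((mat / ii ** 2).sum()) / ns),
        "HGLE": float(((mat * ii ** 2).sum()) / ns),
        "SLGL": float(((mat / (ii ** 2 * jj ** 2)).sum()) / ns),
        "SHGL": float(((mat * ii ** 2 / jj ** 2).sum()) / ns),
        "LLGL": float(((mat * jj ** 2 / ii ** 2).sum()) / ns),
        "LHGL": float(((mat * ii ** 2 * jj ** 2).sum()) / ns),
    }


_GLRLM_NAME_MAP = {
    "SE": "ShortRunEmphasis", "LE": "LongRunEmphasis",
    "GLN": "GrayLevelNonUniformity", "GLNN": "GrayLevelNonUniformityNormalized",
    "N": "RunLengthNonUniformity", "NN": "RunLengthNonUniformityNormalized",
    "Perc": "RunPercentage", "GLV": "GrayLevelVariance", "V": "RunVariance",
    "Entropy": "RunEntropy",
    "LGLE": "LowGrayLevelRunEmphasis", "HGLE": "HighGrayLevelRunEmphasis",
    "SLGL": "ShortRunLowGrayLevelEmphasis", "SHGL": "ShortRunHighGrayLevelEmphasis",
    "LLGL": "LongRunLowGrayLevelEmphasis", "LHGL": "LongRunHighGrayLevelEmphasis",
}

_GLSZM_NAME_MAP = {
    "SE": "SmallAreaEmphasis", "LE": "LargeAreaEmphasis",
    "GLN": "GrayLevelNonUniformity", "GLNN": "GrayLevelNonUniformityNormalized",
    "N": "SizeZoneNonUniformity", "NN": "SizeZoneNonUniformityNormalized",
    "Perc": "ZonePercentage", "GLV": "GrayLevelVariance", "V": "ZoneVariance",
    "Entropy": "ZoneEntropy",
    "LGLE": "LowGrayLevelZoneEmphasis", "HGLE": "HighGrayLevelZoneEmphasis",
    "SLGL": "SmallAreaLowGrayLevelEmphasis", "SHGL": "SmallAreaHighGrayLevelEmphasis",
    "LLGL": "LargeAreaLowGrayLevelEmphasis", "LHGL": "LargeAreaHighGrayLevelEmphasis",
}


def glrlm_features(matrices: list[np.ndarray], n_voxels: int) -> dict[str, float]:
    per_dir = [_rlm_szm_features(m, n_voxels, "run") for m in matrices]
    keys = per_dir[0].keys()
    mean = {k: float(np.mean([f[k] for f in per_dir])) for k in keys}
    return {_GLRLM_NAME_MAP[k]: v for k, v in mean.items()}


# ---------------------------------------------------------------------------
# GLSZM
# ---------------------------------------------------------------------------

def glszm_matrix(droi: DiscretizedROI) -> np.ndarray:
    """Size-zone count matrix P(level, zone size); 26-connected zones."""
    grid, ng = droi.grid, droi.ng
    max_size = droi.n_voxels
    mat = np.zeros((ng, max_size), dtype=np.float64)
    for g in np.unique(grid[grid > 0]):
        lab, n_zones = ndimage.label(grid == g, structure=_STRUCT26)
        if n_zones == 0:
            continue
        sizes = np.bincount(lab.ravel())[1:]
        for s in sizes:
            mat[g - 1, s - 1] += 1.0
    return mat


def glszm_features(mat: np.ndarray, n_voxels: int) -> dict[str, float]:
    raw = _rlm_szm_features(mat, n_voxels, "zone")
    return {_GLSZM_NAME_MAP[k]: v for k, v in raw.items()}


# ---------------------------------------------------------------------------
# GLDM
# ---------------------------------------------------------------------------

def gldm_matrix(droi: DiscretizedROI, alpha: float = 0.0) -> np.ndarray:
    """Dependence count matrix P(level, dependence + 1).

    The dependence of a voxel is the number of its in-ROI 26-neighbors whose
    level differs from the center level by at most ``alpha``.
    """
    grid = droi.grid
    dep = np.zeros(grid.shape, dtype=np.int64)
    for d in ANGLES:
        for dd in (d, tuple(-c for c in d)):
            sa, sb = _offset_slices(grid.shape, dd)
            a, b = grid[sa], grid[sb]
            ok = (a > 0) & (b > 0) & (np.abs(a - b) <= alpha)
            dep[sa] += ok
    mask = grid > 0
    mat = np.zeros((droi.ng, 27), dtype=np.float64)
    np.add.at(mat, (grid[mask] - 1, dep[mask]), 1.0)
    return mat


def gldm_features(mat: np.ndarray) -> dict[str, float]:
    n = mat.sum()
    i = np.arange(1, mat.shape[0] + 1, dtype=np.float64)
    j = np.arange(1, mat.shape[1] + 1, dtype=np.float64)  # dependence + 1
    ii, jj = np.meshgrid(i, j, indexing="ij")
    p = mat / n
    p_i, p_j = p.sum(1), p.sum(0)
    mu_i, var_i = _weighted_moments(p_i, i)
    mu_j, var_j = _weighted_moments(p_j, j)
    return {
        "SmallDependenceEmphasis": float((mat / jj ** 2).sum() / n),
        "LargeDependenceEmphasis": float((mat * jj ** 2).sum() / n),
        "GrayLevelNonUniformity": float((mat.sum(1) ** 2).sum() / n),
        "DependenceNonUniformity": float((mat.sum(0) ** 2).sum() / n),
        "DependenceNonUniformityNormalized": float((mat.sum(0) ** 2).sum() / n ** 2),
        "GrayLevelVariance": var_i,
        "DependenceVariance": var_j,
        "DependenceEntropy": _entropy(p),
        "LowGrayLevelEmphasis": float((mat / ii ** 2).sum() / n),
        "HighGrayLevelEmphasis": float((mat * ii ** 2).sum() / n),
        "SmallDependenceLowGrayLevelEmphasis": float((mat / (ii ** 2 * jj ** 2)).sum() / n),
        "SmallDependenceHighGrayLevelEmphasis": float((mat * ii ** 2 / jj ** 2).sum() / n),
        "LargeDependenceLowGrayLevelEmphasis": float((mat * jj ** 2 / ii ** 2).sum() / n),
        "LargeDependenceHighGrayLevelEmphasis": float((mat * ii ** 2 * jj ** 2).sum() / n),
    }


# ---------------------------------------------------------------------------
# NGTDM
# ---------------------------------------------------------------------------

def ngtdm_table(droi: DiscretizedROI) -> tuple[np.ndarray, np.ndarray, np.ndarray, int]:
    """Per-level (n_i, p_i, s_i) and the number of contributing voxels.

    s_i sums |level - neighborhood mean| over voxels of level i; voxels
    without any valid in-ROI neighbor do not contribute.
    """
    grid = droi.grid
    nb_sum = np.zeros(grid.shape, dtype=np.float64)
    nb_cnt = np.zeros(grid.shape, dtype=np.int64)
    for d in ANGLES:
        for dd in (d, tuple(-c for c in d)):
            sa, sb = _offset_slices(grid.shape, dd)
            a, b = grid[sa], grid[sb]
            ok = (a > 0) & (b > 0)
            nb_sum[sa] += np.where(ok, b, 0)
            nb_cnt[sa] += ok
    mask = (grid > 0) & (nb_cnt > 0)
    nvp = int(mask.sum())
    ng = droi.ng
    n_i = np.zeros(ng)
    s_i = np.zeros(ng)
    levels = grid[mask]
    a_mean = nb_sum[mask] / nb_cnt[mask]
    np.add.at(n_i, levels - 1, 1.0)
    np.add.at(s_i, levels - 1, np.abs(levels - a_mean))
    p_i = n_i / nvp if nvp else n_i
    return n_i, p_i, s_i, nvp


def ngtdm_features(droi: DiscretizedROI) -> dict[str, float]:
    n_i, p_i, s_i, nvp = ngtdm_table(droi)
    ng = len(p_i)
    i = np.arange(1, ng + 1, dtype=np.float64)
    present = p_i > 0
    ngp = int(present.sum())

    ps = float((p_i * s_i).sum())
    coarseness = 1.0 / ps if ps > 0 else _COARSENESS_CAP
    coarseness = min(coarseness, _COARSENESS_CAP)

    if ngp > 1 and nvp > 0:
        pi_, ii_ = p_i[present], i[present]
        si_ = s_i[present]
        diff2 = (ii_[:, None] - ii_[None, :]) ** 2
        contrast = float((pi_[:, None] * pi_[None, :] * diff2).sum()) \
            / (ngp * (ngp - 1)) * float(s_i.sum()) / nvp
        denom = float(np.abs(ii_[:, None] * pi_[:, None] - ii_[None, :] * pi_[None, :]).sum())
        busyness = ps / denom if denom > 0 else 0.0
        absdiff = np.abs(ii_[:, None] - ii_[None, :])
        complexity = float((absdiff * (pi_[:, None] * si_[:, None] + pi_[None, :] * si_[None, :])
                            / (pi_[:, None] + pi_[None, :])).sum()) / nvp
        s_sum = float(s_i.sum())
        strength = float(((pi_[:, None] + pi_[None, :]) * diff2).sum()) / s_sum \
            if s_sum > 0 else 0.0
    else:
        contrast, busyness, complexity, strength = 0.0, 0.0, 0.0, 0.0

    return {
        "Coarseness": float(coarseness),
        "Contrast": contrast,
        "Busyness": busyness,
        "Complexity": complexity,
        "Strength": strength,
    }
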