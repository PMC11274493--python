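"""Independent brute-force reference implementations used only by tests.

Everything here is written as plainly as possible — explicit Python loops
over voxels, level pairs, runs, zones and neighborhoods — so it shares no
code path with the package's vectorized engine. Naming conventions mirror
the package registry so results can be compared key by key.
"""

from __future__ import annotations

import math

import numpy as np

NEIGHBORS_26 = [(dx, dy, dz)
                for dx in (-1, 0, 1) for dy in (-1, 0, 1) for dz in (-1, 0, 1)
                if (dx, dy, dz) != (0, 0, 0)]
DIRECTIONS_13 = [d for d in NEIGHBORS_26 if next(c for c in d if c != 0) > 0]


def _in_bounds(p, shape):
    return all(0 <= p[i] < shape[i] for i in range(3))


def _entropy(values):
    return -sum(v * math.log2(v) for v in values if v > 0)


# ---------------------------------------------------------------------------
# GLCM
# ---------------------------------------------------------------------------

def glcm_counts(grid: np.ndarray, direction, distance: int = 1) -> np.ndarray:
    ng = int(grid.max())
    mat = np.zeros((ng, ng))
    d = tuple(distance * c for c in direction)
    for x in range(grid.shape[0]):
        for y in range(grid.shape[1]):
            for z in range(grid.shape[2]):
                a = grid[x, y, z]
                if a == 0:
                    continue
                q = (x + d[0], y + d[1], z + d[2])
                if not _in_bounds(q, grid.shape):
                    continue
                b = grid[q]
                if b == 0:
                    continue
                mat[a - 1, b - 1] += 1
                mat[b - 1, a - 1] += 1
    return mat


def glcm_features_naive(grid: np.ndarray) -> dict[str, float]:
    ng = int(grid.max())
    per_direction = []
    for d in DIRECTIONS_13:
        counts = glcm_counts(grid, d)
        if counts.sum() == 0:
            continue
        per_direction.append(_glcm_one(counts, ng))
    if not per_direction:
        per_direction.append(_glcm_one(np.zeros((ng, ng)), ng))
    return {k: float(np.mean([f[k] for f in per_direction]))
            for k in per_direction[0]}


def _glcm_one(counts: np.ndarray, ng: int) -> dict[str, float]:
    total = counts.sum()
    p = counts / total if total else counts
    px = [sum(p[i, j] for j in range(ng)) for i in range(ng)]
    py = [sum(p[i, j] for i in range(ng)) for j in range(ng)]
    mu_x = sum((i + 1) * px[i] for i in range(ng))
    mu_y = sum((j + 1) * py[j] for j in range(ng))
    var_x = sum((i + 1 - mu_x) ** 2 * px[i] for i in range(ng))
    var_y = sum((j + 1 - mu_y) ** 2 * py[j] for j in range(ng))
    p_diff = [0.0] * ng
    p_sum = [0.0] * (2 * ng - 1)
    for i in range(ng):
        for j in range(ng):
            p_diff[abs(i - j)] += p[i, j]
            p_sum[i + j] += p[i, j]

    autocorr = sum((i + 1) * (j + 1) * p[i, j] for i in range(ng) for j in range(ng))
    contrast = sum((i - j) ** 2 * p[i, j] for i in range(ng) for j in range(ng))
    if var_x > 0 and var_y > 0:
        correlation = (autocorr - mu_x * mu_y) / math.sqrt(var_x * var_y)
    else:
        correlation = 1.0
    diff_avg = sum(k * p_diff[k] for k in range(ng))
    diff_var = sum((k - diff_avg) ** 2 * p_diff[k] for k in range(ng))
    hxy = _entropy(p.ravel())
    hx, hy = _entropy(px), _entropy(py)
    hxy1 = -sum(p[i, j] * math.log2(px[i] * py[j])
                for i in range(ng) for j in range(ng)
                if p[i, j] > 0 and px[i] * py[j] > 0)
    hxy2 = -sum(px[i] * py[j] * math.log2(px[i] * py[j])
                for i in range(ng) for j in range(ng) if px[i] * py[j] > 0)
    imc1 = (hxy - hxy1) / max(hx, hy) if max(hx, hy) > 0 else 0.0
    imc2 = math.sqrt(max(0.0, 1.0 - math.exp(-2.0 * (hxy2 - hxy))))

    present = [i for i in range(ng) if px[i] > 0]
    if len(present) <= 1 or total == 0:
        mcc = 1.0
    else:
        q = np.zeros((len(present), len(present)))
        for a, i in enumerate(present):
            for b, j in enumerate(present):
                q[a, b] = sum(p[i, k] * p[j, k] / (px[i] * py[k])
                              for k in range(ng) if py[k] > 0)
        eig = sorted(np.real(np.linalg.eigvals(q)), reverse=True)
        mcc = math.sqrt(min(max(eig[1], 0.0), 1.0))

    return {
        "Autocorrelation": autocorr,
        "JointAverage": mu_x,
        "ClusterProminence": sum((i + 1 + j + 1 - mu_x - mu_y) ** 4 * p[i, j]
                                 for i in range(ng) for j in range(ng)),
        "ClusterShade": sum((i + 1 + j + 1 - mu_x - mu_y) ** 3 * p[i, j]
                            for i in range(ng) for j in range(ng)),
        "ClusterTendency": sum((i + 1 + j + 1 - mu_x - mu_y) ** 2 * p[i, j]
                               for i in range(ng) for j in range(ng)),
        "Contrast": contrast,
        "Correlation": correlation,
        "DifferenceAverage": diff_avg,
        "DifferenceEntropy": _entropy(p_diff),
        "DifferenceVariance": diff_var,
        "Id": sum(p_diff[k] / (1.0 + k) for k in range(ng)),
        "Idm": sum(p_diff[k] / (1.0 + k ** 2) for k in range(ng)),
        "Idmn": sum(p_diff[k] / (1.0 + (k / ng) ** 2) for k in range(ng)),
        "Idn": sum(p_diff[k] / (1.0 + k / ng) for k in range(ng)),
        "Imc1": imc1,
        "Imc2": imc2,
        "InverseVariance": sum(p_diff[k] / k ** 2 for k in range(1, ng)),
        "JointEnergy": float((p ** 2).sum()),
        "JointEntropy": hxy,
        "MCC": mcc,
        "MaximumProbability": float(p.max()) if total else 0.0,
        "SumAverage": sum((s + 2) * p_sum[s] for s in range(2 * ng - 1)),
        "SumEntropy": _entropy(p_sum),
        "SumSquares": sum((i + 1 - mu_x) ** 2 * p[i, j]
                          for i in range(ng) for j in range(ng)),
    }


# ---------------------------------------------------------------------------
# GLRLM
# ---------------------------------------------------------------------------

def glrlm_runs(grid: np.ndarray, direction) -> list[tuple[int, int]]:
    """All maximal (level, length) runs along one direction, by walking."""
    runs = []
    shape = grid.shape
    for x in range(shape[0]):
        for y in range(shape[1]):
            for z in range(shape[2]):
                level = grid[x, y, z]
                if level == 0:
                    continue
                prev = (x - direction[0], y - direction[1], z - direction[2])
                if _in_bounds(prev, shape) and grid[prev] == level:
                    continue  # not a run start
                length = 1
                cur = (x + direction[0], y + direction[1], z + direction[2])
                while _in_bounds(cur, shape) and grid[cur] == level:
                    length += 1
                    cur = (cur[0] + direction[0], cur[1] + direction[1],
                           cur[2] + direction[2])
                runs.append((int(level), length))
    return runs


def _rl_sz_one(entries: list[tuple[int, int]], ng: int, n_voxels: int) -> dict[str, float]:
    """Shared run-length/size-zone formulas on (level, size) entries."""
    ns = len(entries)
    if ns == 0:
        return {k: 0.0 for k in
                ("SE", "LE", "GLN", "GLNN", "N", "NN", "Perc", "GLV", "V",
                 "Entropy", "LGLE", "HGLE", "SLGL", "SHGL", "LLGL", "LHGL")}
    max_j = max(j for _, j in entries)
    mat = np.zeros((ng, max_j))
    for i, j in entries:
        mat[i - 1, j - 1] += 1
    p = mat / ns
    row = mat.sum(axis=1)
    col = mat.sum(axis=0)
    mu_i = sum((i + 1) * row[i] / ns for i in range(ng))
    mu_j = sum((j + 1) * col[j] / ns for j in range(max_j))
    return {
        "SE": sum(mat[i, j] / (j + 1) ** 2 for i in range(ng) for j in range(max_j)) / ns,
        "LE": sum(mat[i, j] * (j + 1) ** 2 for i in range(ng) for j in range(max_j)) / ns,
        "GLN": sum(row[i] ** 2 for i in range(ng)) / ns,
        "GLNN": sum(row[i] ** 2 for i in range(ng)) / ns ** 2,
        "N": sum(col[j] ** 2 for j in range(max_j)) / ns,
        "NN": sum(col[j] ** 2 for j in range(max_j)) / ns ** 2,
        "Perc": ns / n_voxels,
        "GLV": sum((i + 1 - mu_i) ** 2 * row[i] / ns for i in range(ng)),
        "V": sum((j + 1 - mu_j) ** 2 * col[j] / ns for j in range(max_j)),
        "Entropy": _entropy(p.ravel()),
        "LGLE": sum(mat[i, j] / (i + 1) ** 2 for i in range(ng) for j in range(max_j)) / ns,
        "HGLE": sum(mat[i, j] * (i + 1) ** 2 for i in range(ng) for j in range(max_j)) / ns,
        "SLGL": sum(mat[i, j] / ((i + 1) ** 2 * (j + 1) ** 2)
                    for i in range(ng) for j in range(max_j)) / ns,
        "SHGL": sum(mat[i, j] * (i + 1) ** 2 / (j + 1) ** 2
                    for i in range(ng) for j in range(max_j)) / ns,
        "LLGL": sum(mat[i, j] * (j + 1) ** 2 / (i + 1) ** 2
                    for i in range(ng) for j in range(max_j)) / ns,
        "LHGL": sum(mat[i, j] * (i + 1) ** 2 * (j + 1) ** 2
                    for i in range(ng) for j in range(max_j)) / ns,
    }


_GLRLM_NAMES = {
    "SE": "ShortRunEmphasis", "LE": "LongRunEmphasis",
    "GLN": "GrayLevelNonUniformity", "GLNN": "GrayLevelNonUniformityNormalized",
    "N": "RunLengthNonUniformity", "NN": "RunLengthNonUniformityNormalized",
    "Perc": "RunPercentage", "GLV": "GrayLevelVariance", "V": "RunVariance",
    "Entropy": "RunEntropy",
    "LGLE": "LowGrayLevelRunEmphasis", "HGLE": "HighGrayLevelRunEmphasis",
    "SLGL": "ShortRunLowGrayLevelEmphasis", "SHGL": "ShortRunHighGrayLevelEmphasis",
    "LLGL": "LongRunLowGrayLevelEmphasis", "LHGL": "LongRunHighGrayLevelEmphasis",
}

_GLSZM_NAMES = {
    "SE": "SmallAreaEmphasis", "LE": "LargeAreaEmphasis",
    "GLN": "GrayLevelNonUniformity", "GLNN": "GrayLevelNonUniformityNormalized",
    "N": "SizeZoneNonUniformity", "NN": "SizeZoneNonUniformityNormalized",
    "Perc": "ZonePercentage", "GLV": "GrayLevelVariance", "V": "ZoneVariance",
    "Entropy": "ZoneEntropy",
    "LGLE": "LowGrayLevelZoneEmphasis", "HGLE": "HighGrayLevelZoneEmphasis",
    "SLGL": "SmallAreaLowGrayLevelEmphasis", "SHGL": "SmallAreaHighGrayLevelEmphasis",
    "LLGL": "LargeAreaLowGrayLevelEmphasis", "LHGL": "LargeAreaHighGrayLevelEmphasis",
}


def glrlm_features_naive(grid: np.ndarray) -> dict[str, float]:
    ng = int(grid.max())
    n_vox = int((grid > 0).sum())
    per_direction = [_rl_sz_one(glrlm_runs(grid, d), ng, n_vox)
                     for d in DIRECTIONS_13]
    mean = {k: float(np.mean([f[k] for f in per_direction]))
            for k in per_direction[0]}
    return {_GLRLM_NAMES[k]: v for k, v in mean.items()}


# ---------------------------------------------------------------------------
# GLSZM (flood-fill zones)
# ---------------------------------------------------------------------------

def glszm_zones(grid: np.ndarray) -> list[tuple[int, int]]:
    """(level, size) of every 26-connected equal-level zone, by flood fill."""
    visited = np.zeros(grid.shape, dtype=bool)
    zones = []
    for x in range(grid.shape[0]):
        for y in range(grid.shape[1]):
            for z in range(grid.shape[2]):
                if grid[x, y, z] == 0 or visited[x, y, z]:
                    continue
                level = grid[x, y, z]
                stack = [(x, y, z)]
                visited[x, y, z] = True
                size = 0
                while stack:
                    cx, cy, cz = stack.pop()
                    size += 1
                    for dx, dy, dz in NEIGHBORS_26:
                        q = (cx + dx, cy + dy, cz + dz)
                        if (_in_bounds(q, grid.shape) and not visited[q]
                                and grid[q] == level):
                            visited[q] = True
                            stack.append(q)
                zones.append((int(level), size))
    return zones


def glszm_features_naive(grid: np.ndarray) -> dict[str, float]:
    ng = int(grid.max())
    n_vox = int((grid > 0).sum())
    raw = _rl_sz_one(glszm_zones(grid), ng, n_vox)
    return {_GLSZM_NAMES[k]: v for k, v in raw.items()}


# ---------------------------------------------------------------------------
# GLDM
# ---------------------------------------------------------------------------

def gldm_features_naive(grid: np.ndarray, alpha: float = 0.0) -> dict[str, float]:
    ng = int(grid.max())
    entries = []
    for x in range(grid.shape[0]):
        for y in range(grid.shape[1]):
            for z in range(grid.shape[2]):
                level = grid[x, y, z]
                if level == 0:
                    continue
                dep = 0
                for dx, dy, dz in NEIGHBORS_26:
                    q = (x + dx, y + dy, z + dz)
                    if (_in_bounds(q, grid.shape) and grid[q] > 0
                            and abs(int(grid[q]) - int(level)) <= alpha):
                        dep += 1
                entries.append((int(level), dep))
    n = len(entries)
    max_d = 27
    mat = np.zeros((ng, max_d))
    for level, dep in entries:
        mat[level - 1, dep] += 1
    p = mat / n
    row = mat.sum(axis=1)
    col = mat.sum(axis=0)
    mu_i = sum((i + 1) * row[i] / n for i in range(ng))
    mu_j = sum((j + 1) * col[j] / n for j in range(max_d))
    return {
        "SmallDependenceEmphasis":
            sum(mat[i, j] / (j + 1) ** 2 for i in range(ng) for j in range(max_d)) / n,
        "LargeDependenceEmphasis":
            sum(mat[i, j] * (j + 1) ** 2 for i in range(ng) for j in range(max_d)) / n,
        "GrayLevelNonUniformity": sum(row[i] ** 2 for i in range(ng)) / n,
        "DependenceNonUniformity": sum(col[j] ** 2 for j in range(max_d)) / n,
        "DependenceNonUniformityNormalized":
            sum(col[j] ** 2 for j in range(max_d)) / n ** 2,
        "GrayLevelVariance": sum((i + 1 - mu_i) ** 2 * row[i] / n for i in range(ng)),
        "DependenceVariance": sum((j + 1 - mu_j) ** 2 * col[j] / n for j in range(max_d)),
        "DependenceEntropy": _entropy(p.ravel()),
        "LowGrayLevelEmphasis":
            sum(mat[i, j] / (i + 1) ** 2 for i in range(ng) for j in range(max_d)) / n,
        "HighGrayLevelEmphasis":
            sum(mat[i, j] * (i + 1) ** 2 for i in range(ng) for j in range(max_d)) / n,
        "SmallDependenceLowGrayLevelEmphasis":
            sum(mat[i, j] / ((i + 1) ** 2 * (j + 1) ** 2)
                for i in range(ng) for j in range(max_d)) / n,
        "SmallDependenceHighGrayLevelEmphasis":
            sum(mat[i, j] * (i + 1) ** 2 / (j + 1) ** 2
                for i in range(ng) for j in range(max_d)) / n,
        "LargeDependenceLowGrayLevelEmphasis":
            sum(mat[i, j] * (j + 1) ** 2 / (i + 1) ** 2
                for i in range(ng) for j in range(max_d)) / n,
        "LargeDependenceHighGrayLevelEmphasis":
            sum(mat[i, j] * (i + 1) ** 2 * (j + 1) ** 2
                for i in range(ng) for j in range(max_d)) / n,
    }


# ---------------------------------------------------------------------------
# NGTDM
# ---------------------------------------------------------------------------

def ngtdm_features_naive(grid: np.ndarray) -> dict[str, float]:
    ng = int(grid.max())
    n_i = [0.0] * ng
    s_i = [0.0] * ng
    nvp = 0
    for x in range(grid.shape[0]):
        for y in range(grid.shape[1]):
            for z in range(grid.shape[2]):
                level = grid[x, y, z]
                if level == 0:
                    continue
                nb = [int(grid[x + dx, y + dy, z + dz])
                      for dx, dy, dz in NEIGHBORS_26
                      if _in_bounds((x + dx, y + dy, z + dz), grid.shape)
                      and grid[x + dx, y + dy, z + dz] > 0]
                if not nb:
                    continue
                nvp += 1
                n_i[level - 1] += 1
                s_i[level - 1] += abs(level - sum(nb) / len(nb))
    p_i = [v / nvp for v in n_i] if nvp else n_i
    present = [i for i in range(ng) if p_i[i] > 0]
    ngp = len(present)
    ps = sum(p_i[i] * s_i[i] for i in range(ng))
    coarseness = min(1.0 / ps if ps > 0 else 1e6, 1e6)
    if ngp > 1 and nvp > 0:
        contrast = (sum(p_i[i] * p_i[j] * (i - j) ** 2
                        for i in present for j in present)
                    / (ngp * (ngp - 1)) * sum(s_i) / nvp)
        denom = sum(abs((i + 1) * p_i[i] - (j + 1) * p_i[j])
                    for i in present for j in present)
        busyness = ps / denom if denom > 0 else 0.0
        complexity = sum(abs(i - j) * (p_i[i] * s_i[i] + p_i[j] * s_i[j])
                         / (p_i[i] + p_i[j])
                         for i in present for j in present) / nvp
        s_sum = sum(s_i)
        strength = (sum((p_i[i] + p_i[j]) * (i - j) ** 2
                        for i in present for j in present) / s_sum
                    if s_sum > 0 else 0.0)
    else:
        contrast = busyness = complexity = strength = 0.0
    return {
        "Coarseness": float(coarseness),
        "Contrast": float(contrast),
        "Busyness": float(busyness),
        "Complexity": float(complexity),
        "Strength": float(strength),
    }


def all_texture_features_naive(grid: np.ndarray) -> dict[str, dict[str, float]]:
    return {
        "glcm": glcm_features_naive(grid),
        "glrlm": glrlm_features_naive(grid),
        "glszm": glszm_features_naive(grid),
        "gldm": gldm_features_naive(grid),
        "ngtdm": ngtdm_features_naive(grid),
    }
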