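"""First-order intensity statistics (18 features).

Moments use the population convention (divide by n). Entropy and uniformity
are computed on the discretized level histogram; everything else on the raw
intensities. Degenerate single-voxel or constant ROIs yield zero variance,
zero entropy and uniformity one (never NaN).
"""

from __future__ import annotations

import numpy as np

from radguide.radiomics._discretize import DiscretizedROI


def firstorder_features(droi: DiscretizedROI) -> dict[str, float]:
    x = droi.values
    n = x.size
    voxel_volume = float(np.prod(droi.spacing))
    mean = float(x.mean())
    m2 = float(((x - mean) ** 2).mean())
    sd = np.sqrt(m2)
    p10, p25, p75, p90 = (float(np.percentile(x, q)) for q in (10, 25, 75, 90))

    if sd > 0:
        skew = float(((x - mean) ** 3).mean()) / sd ** 3
        kurt = float(((x - mean) ** 4).mean()) / m2 ** 2
    else:
        skew, kurt = 0.0, 0.0

    robust = x[(x >= p10) & (x <= p90)]
    if robust.size:
        rmad = float(np.abs(robust - robust.mean()).mean())
    else:  # pragma: no cover - only for pathological percentile ties
        rmad = 0.0

    p = droi.histogram()
    nz = p[p > 0]
    entropy = float(-(nz * np.log2(nz)).sum())
    uniformity = float((p ** 2).sum())

    energy = float((x ** 2).sum())
    return {
        "Energy": energy,
        "TotalEnergy": voxel_volume * energy,
        "Entropy": entropy,
        "Minimum": float(x.min()),
        "10Percentile": p10,
        "90Percentile": p90,
        "Maximum": float(x.max()),
        "Mean": mean,
        "Median": float(np.median(x)),
        "InterquartileRange": p75 - p25,
        "Range": float(x.max() - x.min()),
        "MeanAbsoluteDeviation": float(np.abs(x - mean).mean()),
        "RobustMeanAbsoluteDeviation": rmad,
        "RootMeanSquared": float(np.sqrt((x ** 2).mean())),
        "Skewness": skew,
        "Kurtosis": kurt,
        "Variance": m2,
        "Uniformity": uniformity,
    }
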