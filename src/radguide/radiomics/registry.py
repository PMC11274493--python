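"""Frozen registry of the 107-feature set and its ordering.

The per-ROI feature vector decomposes as 18 first-order + 14 shape +
24 GLCM + 16 GLRLM + 16 GLSZM + 14 GLDM + 5 NGTDM = 107 features. Category
and feature order are frozen here so that tables extracted by different runs
are column-compatible; the registry is the single point of change if the
feature set ever needs to differ.
"""

from __future__ import annotations

import pandas as pd

FIRSTORDER_FEATURES = (
    "Energy", "TotalEnergy", "Entropy", "Minimum", "10Percentile",
    "90Percentile", "Maximum", "Mean", "Median", "InterquartileRange",
    "Range", "MeanAbsoluteDeviation", "RobustMeanAbsoluteDeviation",
    "RootMeanSquared", "Skewness", "Kurtosis", "Variance", "Uniformity",
)

SHAPE_FEATURES = (
    "MeshVolume", "VoxelVolume", "SurfaceArea", "SurfaceVolumeRatio",
    "Sphericity", "Maximum3DDiameter", "Maximum2DDiameterSlice",
    "Maximum2DDiameterColumn", "Maximum2DDiameterRow", "MajorAxisLength",
    "MinorAxisLength", "LeastAxisLength", "Elongation", "Flatness",
)

GLCM_FEATURES = (
    "Autocorrelation", "JointAverage", "ClusterProminence", "ClusterShade",
    "ClusterTendency", "Contrast", "Correlation", "DifferenceAverage",
    "DifferenceEntropy", "DifferenceVariance", "Id", "Idm", "Idmn", "Idn",
    "Imc1", "Imc2", "InverseVariance", "JointEnergy", "JointEntropy",
    "MCC", "MaximumProbability", "SumAverage", "SumEntropy", "SumSquares",
)

GLRLM_FEATURES = (
    "ShortRunEmphasis", "LongRunEmphasis", "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized", "RunLengthNonUniformity",
    "RunLengthNonUniformityNormalized", "RunPercentage",
    "GrayLevelVariance", "RunVariance", "RunEntropy",
    "LowGrayLevelRunEmphasis", "HighGrayLevelRunEmphasis",
    "ShortRunLowGrayLevelEmphasis", "ShortRunHighGrayLevelEmphasis",
    "LongRunLowGrayLevelEmphasis", "LongRunHighGrayLevelEmphasis",
)

GLSZM_FEATURES = (
    "SmallAreaEmphasis", "LargeAreaEmphasis", "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized", "SizeZoneNonUniformity",
    "SizeZoneNonUniformityNormalized", "ZonePercentage",
    "GrayLevelVariance", "ZoneVariance", "ZoneEntropy",
    "LowGrayLevelZoneEmphasis", "HighGrayLevelZoneEmphasis",
    "SmallAreaLowGrayLevelEmphasis", "SmallAreaHighGrayLevelEmphasis",
    "LargeAreaLowGrayLevelEmphasis", "LargeAreaHighGrayLevelEmphasis",
)

GLDM_FEATURES = (
    "SmallDependenceEmphasis", "LargeDependenceEmphasis",
    "GrayLevelNonUniformity", "DependenceNonUniformity",
    "DependenceNonUniformityNormalized", "GrayLevelVariance",
    "DependenceVariance", "DependenceEntropy", "LowGrayLevelEmphasis",
    "HighGrayLevelEmphasis", "SmallDependenceLowGrayLevelEmphasis",
    "SmallDependenceHighGrayLevelEmphasis",
    "LargeDependenceLowGrayLevelEmphasis",
    "LargeDependenceHighGrayLevelEmphasis",
)

NGTDM_FEATURES = ("Coarseness", "Contrast", "Busyness", "Complexity", "Strength")

#: category -> ordered feature names; iteration order is the column order
CATEGORIES: dict[str, tuple[str, ...]] = {
    "firstorder": FIRSTORDER_FEATURES,
    "shape": SHAPE_FEATURES,
    "glcm": GLCM_FEATURES,
    "glrlm": GLRLM_FEATURES,
    "glszm": GLSZM_FEATURES,
    "gldm": GLDM_FEATURES,
    "ngtdm": NGTDM_FEATURES,
}

N_FEATURES_PER_ROI = sum(len(v) for v in CATEGORIES.values())  # 107

REGISTRY_VERSION = "1"


def feature_index() -> list[tuple[str, str]]:
    """Ordered (category, feature) pairs for one ROI."""
    return [(cat, feat) for cat, feats in CATEGORIES.items() for feat in feats]


def registry_frame() -> pd.DataFrame:
    rows = [{"category": c, "feature": f, "registry_version": REGISTRY_VERSION}
            for c, f in feature_index()]
    return pd.DataFrame(rows)
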