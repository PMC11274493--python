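"""Per-ROI feature vectors and whole-atlas feature tables."""

from __future__ import annotations

import numpy as np
import pandas as pd

from radguide.io_core import Atlas, FeatureTable, Volume, radiomics_column
from radguide.radiomics import registry
from radguide.radiomics._discretize import (
    DiscretizationScheme,
    DiscretizedROI,
    discretize_roi,
)
from radguide.radiomics._firstorder import firstorder_features
from radguide.radiomics._shape import shape_features
from radguide.radiomics._texture import (
    glcm_features,
    glcm_matrix,
    gldm_features,
    gldm_matrix,
    glrlm_features,
    glrlm_matrix,
    glszm_features,
    glszm_matrix,
    ngtdm_features,
)


def roi_feature_vector(droi: DiscretizedROI) -> dict[str, float]:
    """All 107 features of one discretized ROI, keyed ``<category>__<name>``."""
    n_vox = droi.n_voxels
    per_cat = {
        "firstorder": firstorder_features(droi),
        "shape": shape_features(droi.mask, droi.spacing),
        "glcm": glcm_features(glcm_matrix(droi)),
        "glrlm": glrlm_features(glrlm_matrix(droi), n_vox),
        "glszm": glszm_features(glszm_matrix(droi), n_vox),
        "gldm": gldm_features(gldm_matrix(droi)),
        "ngtdm": ngtdm_features(droi),
    }
    out: dict[str, float] = {}
    for cat, feat_names in registry.CATEGORIES.items():
        feats = per_cat[cat]
        for name in feat_names:
            v = float(feats[name])
            if not np.isfinite(v):
                raise AssertionError(f"non-finite feature {cat}/{name}: {v}")
            out[f"{cat}__{name}"] = v
    assert len(out) == registry.N_FEATURES_PER_ROI
    return out


def extract_all(volume: Volume, atlas: Atlas,
                scheme: DiscretizationScheme | None = None) -> pd.Series:
    """One subject: per-region 107-feature vectors as a named Series.

    Column order is deterministic: region-table order crossed with the
    frozen registry order.
    """
    scheme = scheme or DiscretizationScheme()
    if volume.data.shape != atlas.labels.shape:
        raise ValueError("volume and atlas shapes differ")
    values: dict[str, float] = {}
    for label, region in atlas.region_table:
        mask = atlas.labels == label
        if not mask.any():
            raise ValueError(f"region label {label} ({region}) has 0 voxels")
        droi = discretize_roi(volume.data, mask, scheme, volume.spacing)
        for key, v in roi_feature_vector(droi).items():
            cat, feat = key.split("__", 1)
            values[radiomics_column(region, cat, feat)] = v
    return pd.Series(values, name=volume.id)


def extract_table(volumes: list[Volume], atlas: Atlas,
                  scheme: DiscretizationScheme | None = None) -> FeatureTable:
    """Radiomics feature table for a list of subjects (rows = subject ids)."""
    rows = [extract_all(v, atlas, scheme) for v in volumes]
    df = pd.DataFrame(rows)
    df.index = [v.id for v in volumes]
    df.index.name = "subject_id"
    return FeatureTable(df)
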