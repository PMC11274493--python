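"""Template-space preprocessing: Gaussian smoothing, SUVR, Z-scoring.

Volumes are assumed already spatially normalized to a common template.
The computational steps implemented here are

* separable Gaussian smoothing parameterised by FWHM in millimetres
  (sigma = FWHM / (2 * sqrt(2 * ln 2)), converted per axis to voxels),
* SUVR normalization — dividing by the mean activity over a brain mask so
  the masked mean becomes exactly 1, and
* feature-table Z-scoring with parameters estimated on the training cohort
  only (population standard-deviation convention, ddof=0, by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from radguide.io_core import FeatureTable, Volume

# FWHM of a Gaussian = 2*sqrt(2*ln 2) * sigma
FWHM_PER_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))


def fwhm_to_sigma(fwhm_mm: float, spacing: tuple[float, float, float]) -> np.ndarray:
    """Per-axis Gaussian sigma in voxel units for a given FWHM in mm."""
    if fwhm_mm < 0:
        raise ValueError(f"FWHM must be >= 0, got {fwhm_mm}")
    spacing = np.asarray(spacing, dtype=np.float64)
    if np.any(spacing <= 0):
        raise ValueError(f"spacing must be positive, got {tuple(spacing)}")
    return (fwhm_mm / FWHM_PER_SIGMA) / spacing


def gaussian_smooth(vol: Volume, fwhm_mm: float) -> Volume:
    """Separable Gaussian smoothing with reflective boundary handling.

    Reflection preserves constant images exactly, which keeps the global
    mean stable on small phantom grids; ``fwhm_mm=0`` is the identity.
    """
    sigma = fwhm_to_sigma(fwhm_mm, vol.spacing)
    if fwhm_mm == 0:
        return Volume(vol.data.copy(), vol.spacing, vol.affine, vol.id)
    sm = ndimage.gaussian_filter(vol.data, sigma=sigma, mode="reflect")
    return Volume(sm, vol.spacing, vol.affine, vol.id)


def suvr_normalize(vol: Volume, brain_mask: np.ndarray) -> Volume:
    """Divide by the mean intensity over ``brain_mask`` (SUVR scaling)."""
    mask = np.asarray(brain_mask, dtype=bool)
    if mask.shape != vol.data.shape:
        raise ValueError("mask shape does not match volume")
    if not mask.any():
        raise ValueError("empty brain mask")
    gm = float(vol.data[mask].mean())
    if gm <= 0:
        raise ValueError(f"nonpositive global mean activity ({gm:g})")
    return Volume(vol.data / gm, vol.spacing, vol.affine, vol.id)


# ---------------------------------------------------------------------------
# feature-table Z-scoring
# ---------------------------------------------------------------------------

@dataclass
class ZScoreParams:
    """Per-feature location/scale fitted on the training cohort.

    Zero-variance features cannot be scaled and are dropped (recorded in
    ``dropped``); ``ddof`` is the standard-deviation convention used.
    """

    mean: pd.Series
    sd: pd.Series
    dropped: list[str] = field(default_factory=list)
    ddof: int = 0

    @property
    def features(self) -> list[str]:
        return list(self.mean.index)


def zscore_fit(train_table: FeatureTable, ddof: int = 0) -> ZScoreParams:
    df = train_table.df
    if len(df) < 2:
        raise ValueError("need >= 2 training rows to fit Z-score parameters")
    mean = df.mean(axis=0)
    sd = df.std(axis=0, ddof=ddof)
    dropped = sd.index[sd.to_numpy() == 0].tolist()
    keep = [c for c in df.columns if c not in set(dropped)]
    return ZScoreParams(mean=mean[keep], sd=sd[keep], dropped=dropped, ddof=ddof)


def zscore_apply(params: ZScoreParams, table: FeatureTable) -> FeatureTable:
    """Transform any table with training-cohort parameters (no refit)."""
    missing = [f for f in params.features if f not in table.df.columns]
    if missing:
        raise ValueError(f"table missing {len(missing)} fitted feature(s), "
                         f"e.g. {missing[:3]}")
    sub = table.df[params.features]
    return FeatureTable((sub - params.mean) / params.sd)


def zscore_invert(params: ZScoreParams, table: FeatureTable) -> FeatureTable:
    sub = table.df[params.features]
    return FeatureTable(sub * params.sd + params.mean)
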