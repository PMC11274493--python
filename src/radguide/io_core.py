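"""Volumes, atlases, manifests and feature tables: reading, writing, contracts.

All volumes are single-channel 3D NIfTI images assumed to live in a common
template space; only voxel spacing is used computationally, the affine is
carried as metadata. Feature tables are plain CSV with subject ids as index;
column names follow the conventions

* ``<region>__<category>__<feature>`` for radiomics features, and
* ``<Family>_Latent_<index>`` for CNN latent features,

so that selection results and interpretation reports can be joined by name.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

logger = logging.getLogger("radguide")

CLASS_LABELS = ("HC", "IPD", "MSA", "PSP")
PATIENT_LABELS = ("IPD", "MSA", "PSP")
SPLITS = ("pretrain", "train", "test")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class Volume:
    """A 3D scalar image with voxel spacing (mm) and affine metadata."""

    data: np.ndarray
    spacing: tuple[float, float, float]
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    id: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError(
                f"expected 3D volume, got {self.data.ndim}D shape {self.data.shape}"
            )
        if min(self.data.shape) < 1:
            raise ValueError(f"degenerate volume shape {self.data.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be three positive values, got {self.spacing}")
        n_nan = int(np.isnan(self.data).sum())
        if n_nan:
            raise ValueError(f"volume contains {n_nan} NaN voxel(s)")
        self.affine = np.asarray(self.affine, dtype=np.float64)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")


@dataclass
class Atlas:
    """Integer label volume (0 = background) plus an ordered region table."""

    labels: np.ndarray
    region_table: list[tuple[int, str]]
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("atlas labels must be a 3D array")
        if not np.issubdtype(self.labels.dtype, np.integer):
            as_int = self.labels.astype(np.int64)
            if not np.array_equal(as_int, self.labels):
                raise ValueError("atlas labels must be integer-valued")
            self.labels = as_int
        self.region_table = [(int(l), str(n)) for l, n in self.region_table]
        tbl_labels = [l for l, _ in self.region_table]
        if len(set(tbl_labels)) != len(tbl_labels):
            raise ValueError("duplicate labels in region table")
        if any(l <= 0 for l in tbl_labels):
            raise ValueError("region labels must be positive integers")
        present = set(np.unique(self.labels).tolist()) - {0}
        missing = sorted(present - set(tbl_labels))
        if missing:
            raise ValueError(
                f"label(s) {missing} present in image but absent from region table"
            )
        self.spacing = tuple(float(s) for s in self.spacing)

    @property
    def n_regions(self) -> int:
        return len(self.region_table)

    @property
    def region_names(self) -> list[str]:
        return [n for _, n in self.region_table]

    def mask(self, label: int) -> np.ndarray:
        return self.labels == label

    def support(self) -> np.ndarray:
        """Union of all labeled voxels (default brain mask for SUVR)."""
        return self.labels > 0


@dataclass
class CohortManifest:
    """Subject table: id, volume path, class label, cohort split."""

    rows: pd.DataFrame

    REQUIRED = ("subject_id", "volume_path", "class_label", "split")

    def __post_init__(self) -> None:
        df = self.rows
        for col in self.REQUIRED:
            if col not in df.columns:
                raise ValueError(f"manifest missing column {col!r}")
        if df["subject_id"].duplicated().any():
            dups = df.loc[df["subject_id"].duplicated(), "subject_id"].tolist()
            raise ValueError(f"duplicate subject ids: {dups}")
        bad = set(df["class_label"]) - set(CLASS_LABELS)
        if bad:
            raise ValueError(f"unknown class label(s): {sorted(bad)}")
        bad = set(df["split"]) - set(SPLITS)
        if bad:
            raise ValueError(f"unknown split(s): {sorted(bad)}")
        # canonical deterministic ordering
        self.rows = df.sort_values("subject_id").reset_index(drop=True)

    def subset(self, split: str) -> "CohortManifest":
        return CohortManifest(self.rows[self.rows["split"] == split].copy())

    def __len__(self) -> int:
        return len(self.rows)


class FeatureTable:
    """Subjects x named features, a thin wrapper over a float DataFrame."""

    def __init__(self, df: pd.DataFrame):
        if df.columns.duplicated().any():
            dups = df.columns[df.columns.duplicated()].tolist()
            raise ValueError(f"duplicate feature columns: {dups}")
        if df.index.duplicated().any():
            raise ValueError("duplicate subject ids in feature table")
        self.df = df.astype(np.float64)

    @property
    def subjects(self) -> list[str]:
        return list(self.df.index)

    @property
    def features(self) -> list[str]:
        return list(self.df.columns)

    @property
    def values(self) -> np.ndarray:
        return self.df.to_numpy()

    @property
    def shape(self) -> tuple[int, int]:
        return self.df.shape

    def __eq__(self, other) -> bool:  # pragma: no cover - convenience
        return isinstance(other, FeatureTable) and self.df.equals(other.df)


def radiomics_column(region: str, category: str, feature: str) -> str:
    """Canonical radiomics column name, e.g. ``putamen__glcm__Contrast``."""
    return f"{region}__{category}__{feature}"


def latent_column(family: str, index: int) -> str:
    """Canonical latent column name, e.g. ``DenseNet_Latent_13280``."""
    return f"{family}_Latent_{int(index)}"


def parse_radiomics_column(name: str) -> tuple[str, str, str]:
    parts = name.split("__")
    if len(parts) != 3:
        raise ValueError(f"not a radiomics column name: {name!r}")
    return parts[0], parts[1], parts[2]


# ---------------------------------------------------------------------------
# volume / atlas I/O
# ---------------------------------------------------------------------------

def read_volume(path: str | Path) -> Volume:
    """Read a 3D single-channel NIfTI volume.

    Raises on missing files, non-3D images and NaN voxels.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"volume not found: {path}")
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float64)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"expected 3D volume, got {data.ndim}D in {path.name}")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return Volume(data=data, spacing=spacing, affine=np.asarray(img.affine), id=path.stem)


def write_volume(vol: Volume, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    affine = np.asarray(vol.affine, dtype=np.float64)
    img = nib.Nifti1Image(vol.data.astype(np.float64), affine)
    img.header.set_zooms(vol.spacing)
    nib.save(img, str(path))
    return path


def read_atlas(path: str | Path, table_path: str | Path) -> Atlas:
    """Read an integer label image and its ``label,region_name`` CSV table."""
    path, table_path = Path(path), Path(table_path)
    if not path.exists():
        raise FileNotFoundError(f"atlas not found: {path}")
    img = nib.load(str(path))
    labels = np.asarray(img.dataobj)
    if labels.ndim == 4 and labels.shape[3] == 1:
        labels = labels[..., 0]
    if not np.allclose(labels, np.round(labels)):
        raise ValueError("atlas image is not integer-valued")
    labels = np.round(labels).astype(np.int64)
    table = pd.read_csv(table_path)
    if not {"label", "region_name"} <= set(table.columns):
        raise ValueError("region table needs columns label,region_name")
    region_table = list(zip(table["label"].astype(int), table["region_name"].astype(str)))
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return Atlas(labels=labels, region_table=region_table, spacing=spacing,
                 affine=np.asarray(img.affine))


def write_atlas(atlas: Atlas, path: str | Path, table_path: str | Path) -> None:
    path, table_path = Path(path), Path(table_path)
    path.parent.mkdir(parents=True, exist_ok=True)
    img = nib.Nifti1Image(atlas.labels.astype(np.int16), np.asarray(atlas.affine))
    img.header.set_zooms(atlas.spacing)
    nib.save(img, str(path))
    pd.DataFrame(atlas.region_table, columns=["label", "region_name"]).to_csv(
        table_path, index=False
    )


# ---------------------------------------------------------------------------
# tables and manifests
# ---------------------------------------------------------------------------

def write_feature_table(table: FeatureTable, path: str | Path) -> Path:
    """CSV round-trip lossless to 12 significant digits."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.df.to_csv(path, index=True, index_label="subject_id",
                    float_format="%.12g")
    return path


def read_feature_table(path: str | Path) -> FeatureTable:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"feature table not found: {path}")
    df = pd.read_csv(path, index_col="subject_id")
    df.index = df.index.astype(str)
    return FeatureTable(df)


def read_manifest(path: str | Path, check_paths: bool = True) -> CohortManifest:
    path = Path(path)
    df = pd.read_csv(path, dtype={"subject_id": str})
    man = CohortManifest(df)
    if check_paths:
        base = path.parent
        for p in man.rows["volume_path"]:
            vp = Path(p)
            if not vp.is_absolute():
                vp = base / vp
            if not vp.exists():
                raise FileNotFoundError(f"manifest references missing volume: {p}")
    return man


def write_manifest(man: CohortManifest, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    man.rows.to_csv(path, index=False)
    return path


def load_volumes(man: CohortManifest, base: str | Path | None = None) -> list[Volume]:
    """Load all manifest volumes in manifest (subject-sorted) order."""
    out = []
    for _, row in man.rows.iterrows():
        p = Path(row["volume_path"])
        if base is not None and not p.is_absolute():
            p = Path(base) / p
        vol = read_volume(p)
        vol.id = str(row["subject_id"])
        out.append(vol)
    return out


# ---------------------------------------------------------------------------
# configs and run metadata
# ---------------------------------------------------------------------------

def read_config(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def write_config(cfg: dict, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(cfg, fh, indent=2, sort_keys=True)
    return path


def config_hash(cfg: dict) -> str:
    blob = json.dumps(cfg, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def write_run_log(path: str | Path, seed: int, cfg: dict | None = None) -> Path:
    """Plain-text run log with seed, config hash and package version."""
    from radguide import __version__

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    lines = [
        f"radguide version: {__version__}",
        f"seed: {seed}",
        f"config hash: {config_hash(cfg or {})}",
    ]
    path.write_text("\n".join(lines) + "\n")
    return path
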