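"""Synthetic SUVR phantom cohorts over a 20-region toy atlas.

The simulator emulates the statistical structure the pipeline assumes in
spatially normalized, smoothed FDG-PET SUVR images: a brain mask containing
20 disjoint regions of interest (four large cortical territories and sixteen
small subcortical/brainstem nuclei), a healthy-control baseline pattern of
regional means, and class-conditional perturbations for the three
Parkinsonian phenotypes:

* MSA — pronounced hypometabolism of the putamen and hindbrain (pons base,
  medulla oblongata),
* PSP — hypometabolism of the caudate, thalamus and midbrain, with a
  frontal-cortex surrogate for the cingulate, and
* IPD — mild diffuse cortical hypometabolism with preserved subcortex.

Affected regions additionally receive a *heterogeneity* multiplier on the
within-region noise standard deviation so that texture features, not only
regional means, carry class signal. Each subject gets multiplicative
per-region random effects (biological variability), voxelwise noise, Gaussian
smoothing at the design FWHM and SUVR normalization (brain-mask mean = 1).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from radguide.io_core import (
    Atlas,
    CohortManifest,
    Volume,
    write_atlas,
    write_manifest,
    write_volume,
)
from radguide.preprocess import gaussian_smooth, suvr_normalize

#: the 20 atlas regions (cortical territories first, then nuclei)
REGION_NAMES = (
    "frontal_cortex",
    "parietal_cortex",
    "occipital_cortex",
    "temporal_cortex",
    "globus_pallidus",
    "nucleus_accumbens",
    "ventral_tegmental",
    "locus_coeruleus",
    "raphe_nucleus",
    "dentate_nucleus",
    "substantia_nigra",
    "red_nucleus",
    "subthalamic_nucleus",
    "caudate",
    "putamen",
    "pallidum",
    "thalamus",
    "medulla_oblongata",
    "midbrain",
    "pons_base",
)

# healthy-control baseline regional means (SUVR-like, background = 1.0);
# values vary across regions so inter-regional contrast exists at baseline
_BASELINE_CORTEX = 1.25
_BASELINE_NUCLEI = (1.35, 1.15, 1.05, 0.95, 1.10, 1.20, 1.00, 1.30,
                    1.05, 1.40, 1.25, 0.95, 1.15, 1.10, 1.30, 1.20)


def default_class_effects() -> dict[str, list[tuple[str, float, float]]]:
    """Class -> [(region, fractional mean shift, heterogeneity multiplier)].

    Magnitudes are design choices: strong enough for the classes to be
    separable at phantom scale, weak enough that classification is not
    trivially perfect at the voxel level.
    """
    return {
        "HC": [],
        "IPD": [
            ("frontal_cortex", -0.05, 1.3),
            ("parietal_cortex", -0.05, 1.3),
            ("occipital_cortex", -0.05, 1.3),
            ("temporal_cortex", -0.05, 1.3),
        ],
        "MSA": [
            ("putamen", -0.15, 1.8),
            ("pons_base", -0.15, 1.8),
            ("medulla_oblongata", -0.15, 1.8),
        ],
        "PSP": [
            ("caudate", -0.12, 1.6),
            ("thalamus", -0.12, 1.6),
            ("midbrain", -0.12, 1.6),
            ("frontal_cortex", -0.12, 1.6),
        ],
    }


@dataclass
class PhantomDesign:
    """Geometry, effects and noise levels of the synthetic cohort."""

    grid_shape: tuple[int, int, int] = (48, 48, 48)
    spacing: tuple[float, float, float] = (2.0, 2.0, 2.0)
    brain_radius_vox: float = 21.0
    cortical_radius_vox: float = 5.0
    nucleus_radius_vox: float = 2.6
    class_effects: dict[str, list[tuple[str, float, float]]] = field(
        default_factory=default_class_effects
    )
    global_noise_sd: float = 0.06
    region_jitter_sd: float = 0.04
    smoothing_fwhm_mm: float = 10.0
    #: smooth first, then SUVR-normalize (switchable to normalize-first)
    smooth_before_suvr: bool = True
    n_per_class: dict[str, dict[str, int]] = field(
        default_factory=lambda: {
            "pretrain": {"HC": 10, "IPD": 10, "MSA": 10, "PSP": 10},
            "train": {"IPD": 50, "MSA": 50, "PSP": 50},
            "test": {"IPD": 25, "MSA": 25, "PSP": 25},
        }
    )
    seed: int = 0

    def __post_init__(self) -> None:
        for cls, effects in self.class_effects.items():
            for region, shift, het in effects:
                if abs(shift) >= 1:
                    raise ValueError(f"|mean_shift| must be < 1 ({cls}:{region})")
                if region not in REGION_NAMES:
                    raise ValueError(f"unknown region in class_effects: {region}")
                if het <= 0:
                    raise ValueError("heterogeneity_scale must be positive")

    def perturbed_regions(self, class_label: str) -> list[str]:
        return [r for r, s, _ in self.class_effects.get(class_label, []) if s != 0]

    def all_perturbed_regions(self) -> set[str]:
        out: set[str] = set()
        for cls in self.class_effects:
            out |= set(self.perturbed_regions(cls))
        return out


def _region_geometry(design: PhantomDesign) -> list[tuple[int, str, tuple[float, float, float], float]]:
    """(label, name, center, radius) for the 20 default spheres."""
    geom = []
    # four cortical spheres in an upper plane
    cortical_xy = [(14, 14), (14, 33), (33, 14), (33, 33)]
    for i in range(4):
        x, y = cortical_xy[i]
        geom.append((i + 1, REGION_NAMES[i], (float(x), float(y), 30.0),
                     design.cortical_radius_vox))
    # sixteen nuclei on two 4x2 planes below
    xs = (13, 20, 27, 34)
    k = 0
    for z in (14, 20):
        for y in (16, 30):
            for x in xs:
                label = 5 + k
                geom.append((label, REGION_NAMES[4 + k], (float(x), float(y), float(z)),
                             design.nucleus_radius_vox))
                k += 1
    return geom


def brain_mask(design: PhantomDesign) -> np.ndarray:
    shape = design.grid_shape
    center = [(s - 1) / 2.0 for s in shape]
    zz = np.indices(shape, dtype=np.float64)
    d2 = sum((zz[i] - center[i]) ** 2 for i in range(3))
    return d2 <= design.brain_radius_vox ** 2


def make_toy_atlas(design: PhantomDesign | None = None) -> Atlas:
    """Build the 20-region toy atlas; regions are validated disjoint and
    well-populated (>= 27 voxels each, so texture matrices are non-trivial)."""
    design = design or PhantomDesign()
    shape = design.grid_shape
    labels = np.zeros(shape, dtype=np.int64)
    mask = brain_mask(design)
    zz = np.indices(shape, dtype=np.float64)
    table = []
    for label, name, center, radius in _region_geometry(design):
        d2 = sum((zz[i] - center[i]) ** 2 for i in range(3))
        sphere = d2 <= radius ** 2
        if not np.all(mask[sphere]):
            raise ValueError(f"region {name} extends outside the brain mask")
        if np.any(labels[sphere] != 0):
            other = int(labels[sphere][labels[sphere] != 0][0])
            raise ValueError(f"region {name} overlaps region label {other}")
        n_vox = int(sphere.sum())
        if n_vox < 27:
            raise ValueError(f"region {name} has only {n_vox} voxels (< 27)")
        labels[sphere] = label
        table.append((label, name))
    affine = np.diag(list(design.spacing) + [1.0])
    return Atlas(labels=labels, region_table=table, spacing=design.spacing,
                 affine=affine)


def _baseline_means() -> dict[str, float]:
    means = {name: _BASELINE_CORTEX for name in REGION_NAMES[:4]}
    means.update(dict(zip(REGION_NAMES[4:], _BASELINE_NUCLEI)))
    return means


def simulate_subject(atlas: Atlas, class_label: str, design: PhantomDesign,
                     rng: np.random.Generator) -> Volume:
    """Simulate one SUVR volume for a subject of the given class.

    The noise-free pattern is piecewise constant (baseline regional means,
    shifted multiplicatively by ``1 + mean_shift`` in affected regions, over
    a uniform brain background); per-region multiplicative random effects and
    voxelwise Gaussian noise are added, then the volume is smoothed at the
    design FWHM and SUVR-normalized over the brain mask.
    """
    if rng is None:
        raise ValueError("an explicit numpy Generator is required")
    if class_label not in design.class_effects:
        raise ValueError(f"unknown class label {class_label!r}")
    effects = {r: (s, h) for r, s, h in design.class_effects[class_label]}
    baseline = _baseline_means()
    mask = brain_mask(design)

    data = np.zeros(design.grid_shape, dtype=np.float64)
    data[mask] = 1.0  # brain background
    noise_sd = np.zeros(design.grid_shape, dtype=np.float64)
    noise_sd[mask] = design.global_noise_sd

    for label, name in atlas.region_table:
        region = atlas.labels == label
        shift, het = effects.get(name, (0.0, 1.0))
        jitter = rng.normal(0.0, design.region_jitter_sd)
        data[region] = baseline[name] * (1.0 + shift) * (1.0 + jitter)
        noise_sd[region] = design.global_noise_sd * het

    data = data + rng.normal(size=design.grid_shape) * noise_sd
    data[~mask] = 0.0
    data = np.clip(data, 1e-6, None) * mask  # activity is nonnegative

    affine = np.diag(list(design.spacing) + [1.0])
    vol = Volume(data, design.spacing, affine)
    if design.smooth_before_suvr:
        vol = gaussian_smooth(vol, design.smoothing_fwhm_mm)
        vol = suvr_normalize(vol, mask)
    else:
        vol = suvr_normalize(vol, mask)
        vol = gaussian_smooth(vol, design.smoothing_fwhm_mm)
    return vol


@dataclass
class SyntheticCohort:
    """Manifest plus ground truth (class and per-region applied shifts)."""

    manifest: CohortManifest
    truth: pd.DataFrame
    volumes: dict[str, Volume]
    atlas: Atlas
    design: PhantomDesign


def _subject_rng(design_seed: int, index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([design_seed, index]))


def simulate_cohort(design: PhantomDesign | None = None,
                    out_dir: str | Path | None = None) -> SyntheticCohort:
    """Simulate a full cohort; optionally write volumes/atlas/manifest/truth.

    The pretraining split contains healthy controls (and patients); the
    train/test splits contain only the three patient classes. Subject seeds
    are derived from the design seed so the cohort is reproducible and each
    subject is independent.
    """
    design = design or PhantomDesign()
    atlas = make_toy_atlas(design)
    rows, truth_rows = [], []
    volumes: dict[str, Volume] = {}
    index = 0
    for split in ("pretrain", "train", "test"):
        for cls in ("HC", "IPD", "MSA", "PSP"):
            n = design.n_per_class.get(split, {}).get(cls, 0)
            for j in range(n):
                sid = f"{split}_{cls}_{j:03d}"
                rng = _subject_rng(design.seed, index)
                vol = simulate_subject(atlas, cls, design, rng)
                vol.id = sid
                volumes[sid] = vol
                rows.append({
                    "subject_id": sid,
                    "volume_path": f"volumes/{sid}.nii.gz",
                    "class_label": cls,
                    "split": split,
                })
                shifts = {f"shift__{r}": 0.0 for r in REGION_NAMES}
                for region, shift, _het in design.class_effects[cls]:
                    shifts[f"shift__{region}"] = shift
                truth_rows.append({"subject_id": sid, "class_label": cls, **shifts})
                index += 1
    manifest = CohortManifest(pd.DataFrame(rows))
    truth = pd.DataFrame(truth_rows).sort_values("subject_id").reset_index(drop=True)
    cohort = SyntheticCohort(manifest=manifest, truth=truth, volumes=volumes,
                             atlas=atlas, design=design)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for sid, vol in volumes.items():
            write_volume(vol, out / "volumes" / f"{sid}.nii.gz")
        write_atlas(atlas, out / "atlas.nii.gz", out / "atlas_regions.csv")
        write_manifest(manifest, out / "manifest.csv")
        truth.to_csv(out / "truth.csv", index=False)
    return cohort


def manifest_hash(manifest: CohortManifest) -> str:
    blob = manifest.rows.to_csv(index=False).encode()
    return hashlib.sha256(blob).hexdigest()
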