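# Methods

`radguide` implements a radiomics-guided latent-feature pipeline for the
multi-class differential classification of Parkinsonian phenotypes (IPD,
MSA, PSP; healthy controls in pretraining only) from template-space,
smoothed, SUVR-normalized brain-PET volumes. Because no public cohort of
this kind exists, every stage runs against a synthetic phantom cohort whose
statistical structure mirrors what the pipeline assumes. This note records
the model, the conventions, the tunable parameters and their defaults, and
what the phantom does and does not establish.

## Pipeline overview

1. **Phantom cohort** — SUVR-like volumes on a 48³ grid (2 mm isotropic)
   with a 20-region atlas and class-conditional regional effects.
2. **Preprocessing** — Gaussian smoothing at 10 mm FWHM, SUVR
   normalization (brain-mask mean = 1), training-cohort Z-scoring.
3. **Radiomics** — 107 features per region (18 first-order, 14 shape,
   24 GLCM, 16 GLRLM, 16 GLSZM, 14 GLDM, 5 NGTDM) → 2140 named features.
4. **CNN extractor** — compact 3D residual or densely connected network,
   pretrained on the 4-class task; latent features are the flattened
   last-convolution activations.
5. **Guided selection** — Pearson screen of latent vs radiomics features
   (|r| > 0.4 and Bonferroni-corrected p < 0.05 on the training cohort),
   LASSO ranking, top-k (default 4) refit in an unpenalized one-vs-rest
   logistic model; odds ratios OR = exp(β) with Wald 95% CIs.
6. **Evaluation** — per-class sensitivity, specificity, PPV, NPV by
   one-vs-rest collapse of the 3-class confusion matrix.
7. **Interpretation** — per retained latent, significantly associated
   radiomics features (category, region, r), highlighted at |r| > 0.5.

## Phantom model

Each subject is a piecewise-constant mean image — baseline regional means
over a uniform brain background — perturbed multiplicatively by
class-conditional shifts, plus per-subject multiplicative regional random
effects and voxelwise Gaussian noise, then smoothed and SUVR-normalized.

Default class effects (fractional mean shifts; heterogeneity multiplier on
within-region noise SD in parentheses):

| class | regions | shift |
|---|---|---|
| MSA | putamen, pons base, medulla oblongata | −15 % (×1.8) |
| PSP | caudate, thalamus, midbrain, frontal cortex | −12 % (×1.6) |
| IPD | frontal/parietal/occipital/temporal cortex | −5 % (×1.3) |

Noise defaults: voxel noise SD 0.06 (SUVR units, pre-smoothing),
per-subject regional jitter SD 0.04. The jitter level is the key
calibration: it sets inter-subject biological variability so that the
classes are separable but **not** trivially so. The bracket is explicit:
the weakest class signal (IPD, −5 % over three discriminating cortical
regions) must stay ≈ 2 SD separated one-vs-rest, which requires jitter
≤ 0.05/2 · √3 ≈ 0.043; at much lower jitter every subject of a class is
nearly identical after 10 mm smoothing, the final logistic fit separates
perfectly, and permutation nulls degenerate to cluster-level behavior.
The default takes the largest value consistent with the separability
floor; 4 % regional variability is also a realistic order of magnitude for
FDG-PET SUVR. Texture heterogeneity multipliers make within-region
variance (hence texture features, not only means) carry class signal.

The smoothing→SUVR order is fixed (a `smooth_before_suvr` switch exposes
the alternative). The geometry is deliberately schematic: four large
cortical spheres and sixteen small nuclei inside a spherical brain mask,
each region ≥ 27 voxels so texture matrices are populated.

**What the phantom does not emulate:** anatomically realistic geometry,
scanner/reconstruction effects, partial-volume effects, asymmetric or
spatially graded disease patterns, age/sex covariates, label noise. Passing
tests therefore establish the *mechanics and statistical calibration* of
the pipeline (correct formulas, honest selection, recoverable effects at
realistic SNR), not clinical performance on real cohorts.

## Preprocessing conventions

* σ = FWHM / (2√(2 ln 2)) per axis, in voxel units; separable convolution
  with reflective boundaries (preserves constants; no edge darkening on the
  small grid). FWHM 0 is the identity.
* SUVR divides by the mean over an explicit brain mask (the atlas support
  by default); the reference region is an input rather than a guess, since
  "global activity" is underspecified in practice.
* Z-scoring uses the population SD convention (ddof 0, configurable) and is
  always fitted on the training cohort only; zero-variance features are
  dropped and recorded.

## Radiomics conventions

* Discretization: fixed bin count 32 over the ROI's [min, max] (SUVR is a
  ratio scale without a canonical bin width); fixed-bin-width mode
  available. Fixed bin count makes all texture families invariant to
  intensity shifts x → x + c (property-tested).
* GLCM: Chebyshev distance 1, the 13 unique 3D directions, symmetric
  accumulation, per-direction normalization, features averaged over the
  directions that contain at least one in-ROI pair. GLRLM likewise counts
  per direction and averages. Whether to average or merge matrices is a
  known degree of freedom; averaging is fixed here.
* GLSZM zones and GLDM dependences use 26-connectivity; GLDM α = 0; NGTDM
  neighborhoods are the valid in-ROI 26-neighbors.
* Degenerate single-level ROIs: GLCM correlation and MCC := 1, NGTDM
  coarseness capped at 10⁶, all other 0/0 := 0 — feature vectors are
  NaN-free by contract.
* Shape uses voxel-count volume and voxel-face surface area (not marching
  cubes): exactly testable, and atlas ROIs have fixed shape anyway. Axis
  lengths are 4√λ from the PCA of voxel-center coordinates; maximal 2D
  diameters are computed per fixed-index plane over surface voxels.
* The feature registry (category, name, order) is frozen in
  `radiomics/registry.py`; the 18+14+24+16+16+14+5 = 107 decomposition is
  the single point of change if a different feature set is ever needed.
* Every texture feature is verified against an independent naive-loop
  implementation (explicit voxel/pair/run/zone loops) to 1e-10 on random
  ROIs, and GLCM/GLRLM aggregates are checked invariant under 90° volume
  rotations.

## CNN extractors

The deepnet module is a small, self-contained NumPy neural-network engine
(im2col 3D convolution, batch normalization, ReLU, 2× pooling, Adam,
softmax cross-entropy) with full backpropagation, verified against numeric
gradients. Everything is float32 and driven by seeded NumPy generators, so
pretraining and extraction are bit-reproducible on CPU.

* **Residual family**: stem conv + max pool, then residual blocks of two
  3³ convolutions with batch norm and ReLU; channels double stage by stage
  with stride-2 downsampling. Eight blocks give 18 weight layers (stem +
  16 + classification layer).
* **Dense family** (default): stem conv + max pool, four dense blocks
  (each layer BN→ReLU→conv3³, growth rate 6, outputs concatenated),
  transition layers (1³ compression conv; average pooling while the map is
  ≥ 6 voxels wide). Default config on 48³ input yields a 3³ × 24-channel
  last map → 648 latent features.
* Latent features = flattened last convolutional feature map (before
  global pooling), evaluation mode with frozen BN statistics, named
  `<Family>_Latent_<index>`.
* Defaults: base width 16 (residual) / growth 6 (dense), ≲ 300k
  parameters, Adam lr 1e-3. Pretraining is the 4-class task since the
  pretraining split contains healthy controls; a binary HC-vs-patient mode
  is not needed for any shipped analysis. The phantom study runs use 20
  epochs at batch size 8 (10 subjects per class in the pretraining split),
  which reliably brings the 4-class loss from ~1.4 to ≲ 0.7; these sizes
  are the package's standard study configuration.

## Guided selection

* Screen: all latent × radiomics pairs on the training cohort; Pearson r
  with two-sided p from the t distribution (n−2 df). Bonferroni
  multiplicity m counts **all tested pairs** (the conservative reading; a
  per-latent mode exists). Constant features are excluded from the screen
  and from m. Retention = ∃ pair with |r| > 0.4 ∧ corrected p < 0.05.
* Ranking: one-vs-rest L1 logistic models (liblinear), penalty chosen by
  5-fold CV on one-vs-rest deviance over a 9-point log grid; rank score =
  max |coefficient| over classes; ties broken by the screen's max |r|,
  then name. If the chosen penalty zeroes everything, ranking falls back
  to screen order (same tie-break chain).
* Final model: unpenalized one-vs-rest logistic fits (Newton) on the top-k
  latents; OR = exp(β), Wald CI = exp(β ± 1.96 SE), two-sided Wald p.
  "Multinomial LR with one-vs-rest" is internally tensioned as a phrase;
  one-vs-rest binary fits with normalized scores match per-class OR tables
  and are what is implemented (a softmax-multinomial variant was judged
  redundant). Quasi-separation (|β| > 30 during Newton) triggers a flagged
  ridge refit (λ = 1) with SEs from the penalized information matrix.
* Baseline radiomics model: penalty fixed once by 5-fold CV on the full
  training table, then n_iter (default 500) randomized stratified 80/20
  splits; features with any nonzero one-vs-rest coefficient are counted;
  the optimal set is the top n_select (default 35) by selection frequency
  (ties lexicographic); final unpenalized one-vs-rest refit on the full
  cohort.

## Evaluation and interpretation

Multi-class metrics collapse one-vs-rest: sens = TP/(TP+FN), spec =
TN/(TN+FP), PPV, NPV per class over the three patient classes in fixed
order (IPD, MSA, PSP). Zero-denominator ratios are reported as missing,
never 0. Weighted sensitivity equals overall accuracy (tested). Nested CV
keeps hyperparameter selection strictly inside outer training folds.

Interpretation reports reuse the screen's corrected p-values (a raw-p flag
exists, since reporting conventions differ); the |r| > 0.5 highlight
threshold is configurable. Reports are pure functions of the persisted
pair table, retained set and thresholds.

**Permutation controls.** Refitting the supervised stages (LASSO ranking
and the logistic model — the screen is label-free) with permuted training
labels gives a leakage control: across permutations the mean per-class
test sensitivity is at chance (1/K). A caveat worth stating explicitly:
the *distribution* of a single permutation draw is overdispersed relative
to an iid binomial with p = 1/K, for two compounding reasons — all test
subjects share one fitted coefficient vector, and subjects of the same
class cluster in feature space, so a permuted-label model tends to assign
whole classes to accidental plurality labels. Any cohort separable enough
to classify well exhibits this; binomial bands on single permutation draws
are therefore anti-conservative for per-class sensitivity, and the mean
over permutation replicates is the reliable leakage statistic.

## Problem sizes and reproducibility

The shipped study configuration simulates, per seed: 40 pretraining
subjects (10 per class, incl. HC), 150 training and 75 test subjects (three
patient classes), at 48³/2 mm. One full pipeline run takes ~1.5 min on a
single CPU core; the test suite runs five seeds and shares them across the
recovery and permutation-null analyses. The acceptance script
(`scripts/acceptance.py`) reruns the baseline radiomics selection study
(500 randomized CV iterations on the 150-subject training table) from
scratch for a given `--seed`.

Known limitations: the phantom's schematic geometry and independent-voxel
noise understate spatial autocorrelation structure of real PET; the NumPy
CNN engine is CPU-bound and not meant for 96³/121-layer scale training;
Wald CIs (not profile likelihood) are reported; GLDM is included to
complete the 107-feature decomposition although texture family membership
of a given published feature list can vary.

One in-print arithmetic note: among published standardized-coefficient /
OR pairs used as identity checks, exp(−2.161) = 0.115 and exp(−0.740) =
0.477 round to 0.12 and 0.48, not the printed 0.11 and 0.47; these two
pairs are treated as printing errata and excluded from identity checks.
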