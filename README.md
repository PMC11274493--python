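# radguide

**Radiomics-guided latent-feature selection for multi-class brain-PET
phenotype classification.**

Differentiating idiopathic Parkinson's disease (IPD) from the atypical
Parkinsonian syndromes multiple system atrophy (MSA) and progressive
supranuclear palsy (PSP) on FDG-PET is clinically hard, and deep 3D CNNs
that do it well are black boxes. `radguide` implements a pipeline that
keeps the CNN's discriminative power while making its features readable:
CNN latent features are kept **only if they correlate strongly with
handcrafted radiomics features** — quantities with explicit formulas and
anatomical locations — and the final classifier is a small logistic model
whose odds ratios can be reported per feature and class.

The package is for methodologists and imaging scientists who want to study
or extend this selection strategy offline: every stage runs against a
built-in synthetic phantom cohort (no patient data required), and every
texture formula is verified against an independent brute-force
implementation.

## The method

For a training cohort with latent features $z_j$ (the flattened last
convolutional activations of a 3D CNN pretrained on the 4-class task
HC/IPD/MSA/PSP) and radiomics features $x_i$ (107 features per atlas
region: first-order, shape, GLCM, GLRLM, GLSZM, GLDM, NGTDM — 2140 over 20
regions):

1. **Correlation screen.** Compute Pearson $r(z_j, x_i)$ for all pairs;
   retain $z_j$ iff some pair has $|r| > 0.4$ and Bonferroni-corrected
   $p < 0.05$ (multiplicity = number of tested pairs).
2. **LASSO ranking.** Rank retained latents by
   $\max_c |\beta^{L1}_{jc}|$ from one-vs-rest L1 logistic models, penalty
   chosen by inner 5-fold cross-validation.
3. **Guided model.** Refit the top $k{=}4$ latents in unpenalized
   one-vs-rest logistic models; report $\mathrm{OR} = e^{\beta}$ with Wald
   95% CIs $e^{\beta \pm 1.96\,\mathrm{SE}}$ per (feature, class).
4. **Interpretation.** For each retained latent, list its significantly
   associated radiomics features (category, brain region, $r$),
   highlighting $|r| > 0.5$.

A baseline radiomics-only model (500 randomized stratified 80/20 LASSO
iterations; top 35 features by selection frequency) provides the reference
the guided model is compared against. Performance is reported as per-class
sensitivity, specificity, PPV and NPV.

## Worked example

`examples/04_guided_selection.py` runs the pipeline end to end on a
reduced phantom cohort (60 training / 30 test patients) and prints:

```
screen: 573 of 648 latents retained (m = 1205280 Bonferroni pairs)
model features: DenseNet_Latent_193, DenseNet_Latent_163, DenseNet_Latent_190, DenseNet_Latent_42

feature               class     beta        OR                95% CI        p
DenseNet_Latent_193   IPD     -2.517    0.0807      (0.00874, 0.745)    0.026
DenseNet_Latent_190   IPD     -3.259    0.0384       (0.00359, 0.41)    0.007
DenseNet_Latent_193   PSP      1.579      4.85            (1.31, 18)    0.018
DenseNet_Latent_163   PSP     -1.496     0.224        (0.067, 0.748)    0.015
...

test-split metrics (one-vs-rest):
     sensitivity  specificity    ppv    npv
IPD          0.9         1.00  1.000  0.952
MSA          1.0         1.00  1.000  1.000
PSP          1.0         0.95  0.909  1.000
```

Reading: the screen kept the latents that are interpretable through
radiomics; the LASSO kept four; `OR = 4.85` for PSP means one standard
deviation of `DenseNet_Latent_193` multiplies the odds of PSP nearly
five-fold (its Wald CI excludes 1), while the same latent lowers the odds
of IPD. `examples/05_interpretation_report.py` then shows which regional
texture features each retained latent tracks — in the phantom, regions
that were truly perturbed by the simulated disease effects (midbrain,
pons base, cortex), e.g.:

```
DenseNet_Latent_24: 11 significant associations, 11 with |r| > 0.5
    firstorder   Median                           midbrain             r=+0.704
    firstorder   Mean                             midbrain             r=+0.694
```

The other examples cover the phantom simulator (`01`), the radiomics
engine (`02`), CNN pretraining (`03`), and the interpretation report
(`05`). The same stages are available as a CLI for file-based workflows:
`radguide simulate / extract / train / latent / guide / evaluate /
interpret` (see `radguide --help`).

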