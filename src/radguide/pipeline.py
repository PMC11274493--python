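"""End-to-end orchestration of the radiomics-guided pipeline on a cohort.

Stages: simulate (or load) a cohort; pretrain the CNN extractor on the
pretraining split (which contains healthy controls); extract latent features
for the train/test splits; extract radiomics features for the training
split; Z-score both tables with training-cohort parameters; screen latents
against radiomics; rank and retain top-k latents; fit the one-vs-rest
logistic model; evaluate on the test split; build the interpretation report.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from radguide.deepnet import (
    ArchConfig,
    TrainConfig,
    TrainedExtractor,
    build_extractor,
    latent_table,
    pretrain,
)
from radguide.evaluation import metrics_from_labels
from radguide.guided_selection import (
    CorrelationScreenResult,
    GuidedModel,
    correlation_screen,
    fit_guided_model,
    predict,
)
from radguide.interpretation import InterpretationReport, build_report
from radguide.io_core import FeatureTable
from radguide.phantom import PhantomDesign, SyntheticCohort, simulate_cohort
from radguide.preprocess import zscore_apply, zscore_fit
from radguide.radiomics import DiscretizationScheme, extract_table


@dataclass
class PipelineResult:
    cohort: SyntheticCohort
    extractor: TrainedExtractor
    latent_train: FeatureTable        # Z-scored, training cohort
    latent_test: FeatureTable         # Z-scored with training parameters
    radiomics_train: FeatureTable     # Z-scored, training cohort
    screen: CorrelationScreenResult
    model: GuidedModel
    test_predictions: list[str]
    test_labels: list[str]
    test_metrics: pd.DataFrame
    report: InterpretationReport


def run_guided_pipeline(seed: int,
                        design: PhantomDesign | None = None,
                        arch: ArchConfig | None = None,
                        train_config: TrainConfig | None = None,
                        k: int = 4,
                        scheme: DiscretizationScheme | None = None) -> PipelineResult:
    """Run the full guided pipeline on a seeded phantom cohort."""
    design = design or PhantomDesign(seed=seed)
    arch = arch or ArchConfig(family="densenet", seed=seed)
    train_config = train_config or TrainConfig(seed=seed)
    cohort = simulate_cohort(design)

    pre = cohort.manifest.subset("pretrain")
    pre_vols = [cohort.volumes[s] for s in pre.rows.subject_id]
    network = build_extractor(arch)
    extractor = pretrain(network, pre_vols, list(pre.rows.class_label), train_config)

    tr_man = cohort.manifest.subset("train")
    te_man = cohort.manifest.subset("test")
    tr_vols = [cohort.volumes[s] for s in tr_man.rows.subject_id]
    te_vols = [cohort.volumes[s] for s in te_man.rows.subject_id]
    tr_labels = list(tr_man.rows.class_label)
    te_labels = list(te_man.rows.class_label)

    lat_tr_raw = latent_table(extractor, tr_vols)
    lat_te_raw = latent_table(extractor, te_vols)
    zs_lat = zscore_fit(lat_tr_raw)
    lat_tr = zscore_apply(zs_lat, lat_tr_raw)
    lat_te = zscore_apply(zs_lat, lat_te_raw)

    rad_tr_raw = extract_table(tr_vols, cohort.atlas, scheme)
    zs_rad = zscore_fit(rad_tr_raw)
    rad_tr = zscore_apply(zs_rad, rad_tr_raw)

    screen = correlation_screen(lat_tr, rad_tr)
    model = fit_guided_model(lat_tr, tr_labels, screen, k=k, seed=seed)
    preds, _probs = predict(model, lat_te)
    metrics = metrics_from_labels(te_labels, preds)
    report = build_report(screen, model)
    return PipelineResult(
        cohort=cohort, extractor=extractor, latent_train=lat_tr,
        latent_test=lat_te, radiomics_train=rad_tr, screen=screen,
        model=model, test_predictions=preds, test_labels=te_labels,
        test_metrics=metrics, report=report,
    )


def refit_with_labels(result: PipelineResult, train_labels: list[str],
                      k: int = 4, seed: int = 0) -> tuple[GuidedModel, list[str], pd.DataFrame]:
    """Refit selection + logistic model with alternative training labels.

    The correlation screen is label-free, so it is reused; only the LASSO
    ranking and the logistic fit depend on labels. Used for permutation
    (null-safety) controls.
    """
    model = fit_guided_model(result.latent_train, train_labels, result.screen,
                             k=k, seed=seed)
    preds, _ = predict(model, result.latent_test)
    metrics = metrics_from_labels(result.test_labels, preds)
    return model, preds, metrics
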