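"""Shared fixtures: phantom designs, cohorts and full pipeline runs.

The expensive five-seed pipeline runs are session-scoped and shared between
the recovery, null-safety and interpretation-level tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from radguide.deepnet import TrainConfig
from radguide.phantom import PhantomDesign, make_toy_atlas, simulate_cohort
from radguide.pipeline import run_guided_pipeline

PIPELINE_SEEDS = (0, 1, 2, 3, 4)


def study_train_config(seed: int) -> TrainConfig:
    """Pretraining schedule used for the phantom study runs."""
    return TrainConfig(epochs=20, batch_size=8, seed=seed)


@pytest.fixture(scope="session")
def default_design() -> PhantomDesign:
    return PhantomDesign()


@pytest.fixture(scope="session")
def toy_atlas(default_design):
    return make_toy_atlas(default_design)


@pytest.fixture(scope="session")
def small_design() -> PhantomDesign:
    """A reduced cohort for fast end-to-end smoke tests."""
    return PhantomDesign(
        n_per_class={
            "pretrain": {"HC": 3, "IPD": 3, "MSA": 3, "PSP": 3},
            "train": {"IPD": 8, "MSA": 8, "PSP": 8},
            "test": {"IPD": 4, "MSA": 4, "PSP": 4},
        },
        seed=123,
    )


@pytest.fixture(scope="session")
def small_cohort(small_design):
    return simulate_cohort(small_design)


@pytest.fixture(scope="session")
def pipeline_results():
    """Full guided-pipeline runs on the default phantom cohort, five seeds."""
    return {
        s: run_guided_pipeline(seed=s, design=PhantomDesign(seed=s),
                               train_config=study_train_config(s))
        for s in PIPELINE_SEEDS
    }
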