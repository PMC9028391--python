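"""Shared fixtures: small synthetic cohorts and pipeline runs.

Everything is generated at test time; the heavier end-to-end fixtures are
session-scoped so the pipeline runs once and is reused.
"""

from __future__ import annotations

import numpy as np
import pytest

from thyromsi.model import default_mz_grid
from thyromsi.pipeline import run_pipeline
from thyromsi.synthetic import (
    CohortConfig,
    NoiseModel,
    make_class_templates,
)


@pytest.fixture(scope="session")
def grid_3da() -> np.ndarray:
    return default_mz_grid(3.0)


@pytest.fixture(scope="session")
def templates_disjoint():
    return make_class_templates(rng_seed=5, n_peaks_per_class=8, shared_peak_fraction=0.0)


@pytest.fixture(scope="session")
def templates_shared():
    return make_class_templates(rng_seed=5, n_peaks_per_class=10, shared_peak_fraction=0.3)


@pytest.fixture(scope="session")
def noiseless_config() -> CohortConfig:
    """Disjoint templates, zero noise: the pipeline must be perfect here."""
    return CohortConfig(
        n_hp_train=4,
        n_ht_train=2,
        n_ptc_train=3,
        validation_counts={"TIR2": 2, "TIR3": 2, "TIR4": 1, "TIR5": 2},
        pixels_per_nodule=64,
        rois_per_nodule=3,
        mz_step=3.0,
        shared_peak_fraction=0.0,
        noise=NoiseModel.noiseless(),
        rng_seed=11,
    )


@pytest.fixture(scope="session")
def noiseless_result(noiseless_config):
    return run_pipeline(noiseless_config)


@pytest.fixture(scope="session")
def noisy_config() -> CohortConfig:
    """Small realistic cohort: default noise, partially shared templates."""
    return CohortConfig(
        n_hp_train=6,
        n_ht_train=3,
        n_ptc_train=4,
        validation_counts={"TIR2": 3, "TIR3": 5, "TIR4": 2, "TIR5": 3},
        pixels_per_nodule=80,
        rois_per_nodule=3,
        mz_step=3.0,
        rng_seed=1,
    )


@pytest.fixture(scope="session")
def noisy_result(noisy_config):
    return run_pipeline(noisy_config)
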