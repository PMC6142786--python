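"""Shared fixtures: small synthetic cohorts and canonical epochs."""

import numpy as np
import pytest

from sleepforest.features import FeatureConfig, extract_feature_matrix
from sleepforest.synthetic import SimulationConfig, generate_dataset, generate_epoch


@pytest.fixture(scope="session")
def small_cohort():
    """2 subjects per gender x 30 epochs, fixed seed."""
    config = SimulationConfig(n_subjects_per_gender=2, epochs_per_subject=30, seed=42)
    epochs, meta = generate_dataset(config)
    return epochs, meta, config


@pytest.fixture(scope="session")
def small_feature_table(small_cohort):
    epochs, meta, _ = small_cohort
    return extract_feature_matrix(epochs, meta, FeatureConfig())


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def one_epoch_per_stage():
    rng = np.random.default_rng(7)
    return {
        stage: generate_epoch(stage, rng=rng)
        for stage in ("WA", "NREM1", "NREM2", "NREM3", "NREM4", "REM")
    }


def logistic_map(n: int, x0: float = 0.4) -> np.ndarray:
    """Fully chaotic logistic map x_{n+1} = 4 x_n (1 - x_n)."""
    x = np.empty(n)
    x[0] = x0
    for i in range(n - 1):
        x[i + 1] = 4.0 * x[i] * (1.0 - x[i])
    return x
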