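import warnings

import numpy as np
import pytest

from rootplast.config import EffectConfig, ExperimentDesign, PipelineConfig
from rootplast.pipeline import run_pipeline


@pytest.fixture(scope="session")
def design() -> ExperimentDesign:
    return ExperimentDesign()


@pytest.fixture(scope="session")
def effects() -> EffectConfig:
    return EffectConfig()


@pytest.fixture(scope="session")
def noise_free_effects() -> EffectConfig:
    """Deterministic limit: no residual, block or weighing noise."""
    return EffectConfig(residual_sd=0.0, block_sd=0.0, weighing_sd=0.0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260922)


@pytest.fixture(scope="session")
def pipeline_result():
    """One full default pipeline run (seed 7), shared across tests."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return run_pipeline(PipelineConfig(seed=7))
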