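import numpy as np
import pytest

from bcgsleep.features import FEATURE_NAMES
from bcgsleep.model import ModelConfig, TrainingConfig
from bcgsleep import pipeline as pl
from bcgsleep.synthetic import SyntheticSessionConfig, make_cohort, synthesize_session


@pytest.fixture(scope="session")
def small_session():
    """One 20-min synthetic session with audio and ground-truth hypnogram."""
    cfg = SyntheticSessionConfig(seed=3, duration_s=1200.0)
    session, truth = synthesize_session(cfg)
    return session, truth


@pytest.fixture(scope="session")
def cohort_features():
    """Six 1-h single-session subjects with well-separated stage parameters,
    assembled into per-epoch feature matrices (shared across tests: this is
    the expensive fixture)."""
    base = SyntheticSessionConfig(duration_s=3600.0)
    sessions, truths = make_cohort(n_subjects=6, sessions_each=1,
                                   base_seed=11, base_config=base)
    return pl.extract_features(sessions), truths


@pytest.fixture(scope="session")
def reduced_model_config():
    """Narrow training configuration used for cross-validation runs; the
    full published widths are exercised by the parameter-count tests."""
    return ModelConfig(input_dim=len(FEATURE_NAMES), bilstm_units=(32, 16),
                       n_blocks=2, conv_filters=16, kernel_size=3, n_classes=3)


@pytest.fixture(scope="session")
def training_config():
    return TrainingConfig(max_passes=25, seed=11)


@pytest.fixture(scope="session")
def loso_result(cohort_features, reduced_model_config, training_config):
    """LOSO run on the synthetic cohort, shared by the recovery tests."""
    sf, _ = cohort_features
    return pl.run_loso(sf, reduced_model_config, training_config,
                       three_class=True)
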