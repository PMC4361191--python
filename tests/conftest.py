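"""Shared fixtures: one default-condition pipeline state reused across tests.

Training the two 50-member ensembles takes well under a second, but many
tests inspect the same objects, so everything derived from the default
master seed (0) is session-scoped.
"""

import pytest

from streamdiag import synthdata
from streamdiag.pipeline import (
    PipelineConfig,
    prepare_mesocosm_features,
    train_stage,
    validate_stage,
)

MASTER_SEED = 0


@pytest.fixture(scope="session")
def default_config() -> PipelineConfig:
    return PipelineConfig.default(seed=MASTER_SEED)


@pytest.fixture(scope="session")
def mesocosm_table(default_config):
    return synthdata.generate_mesocosm(default_config.mesocosm)


@pytest.fixture(scope="session")
def mesocosm_features(default_config, mesocosm_table):
    return prepare_mesocosm_features(default_config, mesocosm_table)


@pytest.fixture(scope="session")
def ensembles(default_config, mesocosm_features):
    return train_stage(default_config, mesocosm_features)


@pytest.fixture(scope="session")
def validation_summary(default_config, mesocosm_features, ensembles):
    return validate_stage(default_config, mesocosm_features, ensembles)


@pytest.fixture(scope="session")
def survey_tables(default_config):
    return synthdata.generate_survey(default_config.survey, default_config.mesocosm)
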