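import numpy as np
import pytest

from emgpr import (SessionPlan, SimConfig, ThresholdConfig,
                   extract_training_set, fit_lda, make_training_session)


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


@pytest.fixture(scope="session")
def default_cfg():
    return SimConfig(seed=1)


@pytest.fixture(scope="session")
def trained_model(default_cfg):
    """LDA model fitted on one simulated prompted training session (seed 1)."""
    plan = SessionPlan()
    rec = make_training_session(default_cfg, plan)
    X, y = extract_training_set(rec, plan)
    return fit_lda(X, y, layout={"channel_labels": rec.channel_labels})


@pytest.fixture(scope="session")
def st_thresholds():
    return ThresholdConfig.standard()
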