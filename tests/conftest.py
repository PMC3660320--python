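import numpy as np
import pytest

from scmforage.config import AnalysisConfig, DesignConfig, FullConfig, ScmConfig, ValueParams
from scmforage.scheduler import build_testing_session, build_training_session
from scmforage.synth import simulate_subject


@pytest.fixture
def design():
    return DesignConfig()


@pytest.fixture
def full_config():
    return FullConfig()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def training_log(full_config):
    """One simulated training day for one subject (deterministic)."""
    sched = build_training_session(full_config.design, day_parity=0, seed=11)
    return simulate_subject(sched, full_config.value, full_config.timing, seed=12)


@pytest.fixture
def testing_log_bc(full_config):
    """One simulated B-vs-C testing day (deterministic)."""
    sched = build_testing_session(full_config.design, ("B", "C"), day_parity=0, seed=21)
    return simulate_subject(sched, full_config.value, full_config.timing, seed=22)


@pytest.fixture
def tiny_pipeline_config():
    """Scaled-down pipeline configuration for fast end-to-end tests."""
    return FullConfig(
        scm=ScmConfig(n_experiments=300),
        analysis=AnalysisConfig(n_subjects=2, training_days=1, max_test_days=6),
    )
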