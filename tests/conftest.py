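import numpy as np
import pytest

from photorl.behavior import AgentParams, TaskConfig, simulate_cohort, simulate_site
from photorl.pipeline import GROUP_MEDIANS
from photorl.qfit import compute_q_trajectories


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def median_agent():
    """Group-median agent parameters from fitted mouse behavior."""
    return GROUP_MEDIANS


@pytest.fixture(scope="session")
def small_task():
    return TaskConfig(trials_per_session=150, sessions_per_site=2)


@pytest.fixture(scope="session")
def site_trials(small_task):
    """One site, 300 trials, median agent."""
    rng = np.random.default_rng(99)
    return simulate_site(GROUP_MEDIANS, small_task, rng, site_id="site0")


@pytest.fixture(scope="session")
def cohort_trials(small_task):
    """Three median-parameter sites, 300 trials each."""
    return simulate_cohort([GROUP_MEDIANS] * 3, small_task, seed=7)


@pytest.fixture(scope="session")
def site_qtraj(site_trials):
    return compute_q_trajectories({"site0": GROUP_MEDIANS}, site_trials)
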