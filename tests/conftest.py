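import pytest

from trialae.cohort import GROUP_LABELS
from trialae.synthetic_data import SimulationConfig, generate_cohort
from trialae.vocabulary import default_term_map


@pytest.fixture(scope="session")
def term_map():
    return default_term_map()


@pytest.fixture(scope="session")
def demo_cohort():
    """A 50-trial cohort under the default (illustrative) configuration."""
    return generate_cohort(SimulationConfig(n_trials=50, seed=1234))


@pytest.fixture(scope="session")
def uniform_null_config():
    """Equal incidence, uniform group weights, no group effects."""
    return SimulationConfig(
        n_trials=60,
        seed=99,
        group_incidence={g: 0.25 for g in GROUP_LABELS},
        group_effect={},
        age_group_weights={g: 0.125 for g in GROUP_LABELS},
    )
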