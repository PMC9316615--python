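import pytest

from starlimit.pipeline import scored_frame
from starlimit.synthetic_study import SimConfig, simulate_study


@pytest.fixture(scope="session")
def study():
    """One default-design synthetic study shared across tests."""
    return simulate_study(SimConfig(seed=11))


@pytest.fixture(scope="session")
def scored(study):
    return scored_frame(study.trials)


@pytest.fixture(scope="session")
def novices(scored):
    return scored[scored["cohort"] == "novice"].reset_index(drop=True)
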