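import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_cohort():
    """Six-subject Experiment-1 cohort with default contamination (shared)."""
    from cueddm import ObserverParams, get_design, simulate_cohort

    return simulate_cohort(get_design("E1"), ObserverParams(), 6, 20260926)
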