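import pytest

from pdtask import default_protocol, demo_cohort, simulate_cohort


@pytest.fixture(scope="session")
def rat_protocol():
    return default_protocol("rat")


@pytest.fixture(scope="session")
def marmoset_protocol():
    return default_protocol("marmoset")


@pytest.fixture(scope="session")
def small_rat_log(rat_protocol):
    """Four-subject rat cohort (2 gambler-like, 2 non-gambler-like), fixed seed."""
    agents = demo_cohort("rat", n_gambler=2, n_non_gambler=2)
    return simulate_cohort(agents, rat_protocol, seed=20260920)
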