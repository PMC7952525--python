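import pytest

from ductus.simulate import default_config, generate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """Study-sized synthetic cohort (42 conservative / 21 treated)."""
    return generate_cohort(default_config(seed=1))


@pytest.fixture(scope="session")
def big_cohort_and_config():
    """Large cohort (5000/group) for distribution-level calibration checks."""
    config = default_config(seed=3, n_conservative=5000, n_treated=5000)
    return generate_cohort(config), config
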