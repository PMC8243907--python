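import pytest

import spatialmeth as sm


@pytest.fixture(scope="session")
def default_cohort():
    """One full-size default cohort (9 samples, 3 clones, 50k probes)."""
    return sm.simulate_cohort(sm.default_cohort_config(seed=11))


@pytest.fixture(scope="session")
def small_cohort():
    """Desk-scale cohort for cheap tests; same design, 5k probes."""
    return sm.simulate_cohort(sm.default_cohort_config(seed=7, n_probes=5000))
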