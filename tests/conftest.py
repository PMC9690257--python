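import numpy as np
import pytest

import screenacc as sa


@pytest.fixture(scope="session")
def default_spec():
    return sa.default_cohort_spec(seed=123)


@pytest.fixture(scope="session")
def small_cohort(default_spec):
    """A mid-sized synthetic cohort for pipeline tests."""
    from dataclasses import replace

    return sa.generate_cohort(replace(default_spec, n=3000, seed=42))


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
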