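import numpy as np
import pytest

from crcscreen.natural_history import CohortConfig
from crcscreen.pipeline import ModelInputs
from crcscreen.synthetic import make_fixture_bundle


@pytest.fixture(scope="session")
def bundle():
    return make_fixture_bundle("dr", 0)


@pytest.fixture(scope="session")
def small_inputs(bundle):
    """2,000-person inputs for fast end-to-end checks."""
    return ModelInputs(
        params=bundle.truth_params,
        lifetable=bundle.lifetable,
        survival=bundle.survival,
        costs=bundle.costs,
        tests=bundle.tests,
        weights=bundle.weights,
        strategies=bundle.strategies,
        cohort=CohortConfig(n=2000, seed=11),
    )


@pytest.fixture(scope="session")
def nh_trace(small_inputs):
    from crcscreen.natural_history import simulate_cohort

    i = small_inputs
    return simulate_cohort(i.cohort, i.params, i.lifetable, i.survival, tests=i.tests)
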