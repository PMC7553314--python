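import numpy as np
import pytest

from cellalloc import (
    GrowthModulation,
    gillespie_lineage,
    reference_parameterization,
)


@pytest.fixture(scope="session")
def params():
    return reference_parameterization()


@pytest.fixture(scope="session")
def ref_mod():
    """The fast-growth reference condition (growth rate ~1/hr, no drug/burden)."""
    return GrowthModulation(k=3.5088, label="ref")


@pytest.fixture(scope="session")
def ref_records(params, ref_mod):
    """A long baseline stochastic lineage at the calibrated defaults."""
    return gillespie_lineage(params, ref_mod, n_cycles=4050, seed=20)


@pytest.fixture(scope="session")
def random_states():
    """Random valid cell states (absolute amounts) for property checks."""
    rng = np.random.default_rng(12345)
    states = rng.uniform(0.0, 200.0, size=(1000, 7))
    states[:, 1] += 1.0  # keep E > 0 so V > 0
    return states
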