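"""Shared fixtures: a small synthetic landscape with a known-truth species."""

import numpy as np
import pytest

from disjunctsdm import (generate_climate_stack, generate_scenario_set,
                         make_virtual_species, sample_occurrences)


@pytest.fixture(scope="session")
def stack():
    """100 x 140 km landscape, 6 layers, 1 km cells."""
    return generate_climate_stack(6, (100, 140), autocorr_range=12.0,
                                  cross_corr=0.3, seed=11)


@pytest.fixture(scope="session")
def truth(stack):
    return make_virtual_species(stack)


@pytest.fixture(scope="session")
def occurrences(truth, stack):
    return sample_occurrences(truth, stack, n_core=250, n_disjunct=50, seed=12)


@pytest.fixture(scope="session")
def scenarios(stack):
    """Current plus 2 GCMs x 2 RCPs (kept small for unit tests)."""
    return generate_scenario_set(stack, gcm_ids=("GCM1", "GCM2"), seed=13)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
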