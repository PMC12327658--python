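import numpy as np
import pytest

import bws


@pytest.fixture(scope="session")
def small_items():
    return bws.ItemSet([f"item{i}" for i in range(7)])


@pytest.fixture(scope="session")
def fano_design(small_items):
    """The cyclic (7, 3, 1) design developed from {0, 1, 3}."""
    return bws.develop_design(bws.find_difference_set(7, 3, 1), 7, small_items)


@pytest.fixture(scope="session")
def study_design():
    """The 15-item, 15-set, 7-option balanced design."""
    items = bws.reference_item_set()
    return bws.make_bibd_design(items, n_sets=15, set_size=7)


@pytest.fixture(scope="session")
def study_fixture():
    """Deterministic study-scale bundle: design, 300x15 responses, truth."""
    return bws.make_study_fixture(seed=1)


@pytest.fixture(scope="session")
def study_fit(study_fixture):
    _, dataset, _ = study_fixture
    return bws.fit_maxdiff(dataset)


@pytest.fixture(scope="session")
def reference_utilities():
    return bws.reference_utilities()


@pytest.fixture()
def rng():
    return np.random.default_rng(20260926)
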