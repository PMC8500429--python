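import dataclasses

import numpy as np
import pytest

import dmridesign as dd


@pytest.fixture
def rng():
    return np.random.default_rng(20211008)


@pytest.fixture(scope="session")
def e21_config():
    return dd.load_fixture("E2.1")


@pytest.fixture(scope="session")
def e22_config():
    return dd.load_fixture("E2.2")


@pytest.fixture(scope="session")
def e21_small(e21_config):
    """E2.1 fixture scaled to a fast cohort for structural tests."""
    return dataclasses.replace(e21_config, n_per_tissue=100)


def shrink(config, n, seed=None):
    changes = {"n_per_tissue": n}
    if seed is not None:
        changes["seed"] = seed
    return dataclasses.replace(config, **changes)
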