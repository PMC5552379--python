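import numpy as np
import pytest

import isobolo as ib


@pytest.fixture(scope="session")
def sb_ipl():
    return ib.load_fixture("sb_ipl")


@pytest.fixture(scope="session")
def pha_ipl():
    return ib.load_fixture("pha_ipl")


@pytest.fixture(scope="session")
def pha_it():
    return ib.load_fixture("pha_it")


@pytest.fixture(scope="session")
def combo_ipl_ipl():
    return ib.load_fixture("combo_ipl_ipl")


@pytest.fixture(scope="session")
def combo_ipl_it():
    return ib.load_fixture("combo_ipl_it")


@pytest.fixture
def rng():
    return np.random.default_rng(20170727)


def random_table(rng, n_levels=3, n_per_level=2):
    """Small random dose-effect table for oracle comparisons."""
    doses = np.sort(10.0 ** rng.uniform(-2, 1, size=n_levels))
    doses = np.repeat(doses, n_per_level)
    y = rng.normal(20, 30, size=doses.size)
    return ib.DoseEffectTable.from_arrays("random", doses, y)
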