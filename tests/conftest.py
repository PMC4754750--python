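import warnings

import numpy as np
import pytest

from simdti.datatypes import PredictionConfig
from simdti.fixtures import UniverseSpec, generate_raw_records, generate_universe
from simdti.predictor import sample_gsn


@pytest.fixture(autouse=True)
def _quiet_runtime_warnings():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        yield


@pytest.fixture(scope="session")
def small_universe():
    """Quick planted universe for predictor/evaluation tests."""
    spec = UniverseSpec(
        n_drugs=24, n_proteins=30, n_modules=3, gsp_fraction=0.5, seed=7
    )
    return generate_universe(spec)


@pytest.fixture(scope="session")
def small_gsn(small_universe):
    return sample_gsn(small_universe.gsp, seed=1)


@pytest.fixture(scope="session")
def default_universe():
    """The default planted universe (60 drugs, 80 proteins, 4 modules)."""
    return generate_universe()


@pytest.fixture(scope="session")
def raw_records():
    return generate_raw_records(n_drugs=8, n_proteins=10, seed=3)


@pytest.fixture
def config():
    return PredictionConfig(seed=1)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
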