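import numpy as np
import pytest
from hypothesis import settings

from ddrcycle import CellCycleParams, CellCycleState, PKParams, TumorParams, cycle_seed_state

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture
def params() -> CellCycleParams:
    return CellCycleParams()


@pytest.fixture
def seed_state(params) -> CellCycleState:
    return cycle_seed_state(100.0, params)


@pytest.fixture
def pk_params() -> PKParams:
    return PKParams()


@pytest.fixture
def tumor_params(params) -> TumorParams:
    return TumorParams(cycle=params)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
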