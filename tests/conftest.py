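import numpy as np
import pytest

from stoptask.belief import GenerativeParams
from stoptask.policy import CostParams


@pytest.fixture(scope="session")
def paper_gen() -> GenerativeParams:
    """Default within-trial parameterization used throughout."""
    return GenerativeParams(q_d=0.55, q_s=0.72, q=0.1, r=0.25, D=50, step_ms=22.0)


@pytest.fixture(scope="session")
def paper_cost() -> CostParams:
    return CostParams(c=0.002, c_s=0.4)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
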