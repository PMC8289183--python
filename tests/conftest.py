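import numpy as np
import pytest

from ugnp.config import RunConfig
from ugnp.kinetics import RateParameters, ReactionState


@pytest.fixture
def config() -> RunConfig:
    return RunConfig()


@pytest.fixture
def default_params() -> RateParameters:
    return RateParameters()


@pytest.fixture
def seed_state(config) -> ReactionState:
    """Seed-recipe initial concentrations (0.125 mM Au, 0.1 mM TA)."""
    return config.initial_reaction_state()


@pytest.fixture
def t_grid() -> np.ndarray:
    return np.linspace(0.0, 120.0, 241)
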