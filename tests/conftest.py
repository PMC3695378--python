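import numpy as np
import pytest

from jointsurv import GompertzGenoModel, SimulationDesign


@pytest.fixture
def null_model():
    """Reference Gompertz parameters with no genetic effect."""
    return GompertzGenoModel(log_a=-9.0, b=0.08, gamma=0.0, p0=0.25)


@pytest.fixture
def frailty_model():
    """Reference parameters with a deleterious allele (gamma = 0.4)."""
    return GompertzGenoModel(log_a=-9.0, b=0.08, gamma=0.4, p0=0.25)


@pytest.fixture
def reference_design(frailty_model):
    """The full study design: n = 4500, entry 40-100, 6-year follow-up."""
    return SimulationDesign(model=frailty_model)


@pytest.fixture
def rng():
    return np.random.default_rng(20260922)
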