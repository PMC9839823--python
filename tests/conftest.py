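import numpy as np
import pytest

from rdgrow.kinetics import GrowthLaw, KineticsSpec


@pytest.fixture
def schnakenberg():
    return KineticsSpec("schnakenberg", {"a": 0.01, "b": 1.1})


@pytest.fixture
def gierer_meinhardt():
    return KineticsSpec("gierer_meinhardt", {"a": 0.01, "b": 0.5, "c": 5.5})


@pytest.fixture
def fitzhugh_nagumo():
    return KineticsSpec("fitzhugh_nagumo", {"a": 1.01, "b": 1.0, "c": 1.0, "i0": 1.0})


@pytest.fixture
def logistic():
    return KineticsSpec("logistic")


@pytest.fixture
def bistable():
    return KineticsSpec("bistable")


@pytest.fixture
def zero_kinetics():
    """Pure transport: f identically zero (scalar)."""
    return KineticsSpec(
        "custom",
        n_species=1,
        f=lambda u: np.zeros_like(u),
        jac=lambda u: np.zeros((1, 1)),
    )


@pytest.fixture
def constant_growth():
    def make(s0):
        return GrowthLaw("constant", {"s0": s0})

    return make
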