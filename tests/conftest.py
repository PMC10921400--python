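import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from peroxifit.forcefield import ExclusionPolicy, ForceConstants, ModelParameters


@pytest.fixture
def params():
    """The optimized parameter set."""
    return ModelParameters()


@pytest.fixture
def fc():
    """Arbitrary positive force constants (values are config inputs)."""
    return ForceConstants(kb_OO=2.5e5, kb_OH=4.6e5, ka_HOO=400.0)


@pytest.fixture
def exclude_all():
    return ExclusionPolicy(mode="exclude_all_intra")


@pytest.fixture
def opls_half():
    return ExclusionPolicy(mode="opls_14_half", fudge_qq=0.5)


@pytest.fixture
def rng():
    return np.random.default_rng(1729)
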