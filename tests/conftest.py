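import numpy as np
import pytest

from msnsig.network import MassActionReaction, NetworkModel, SpeciesDef


@pytest.fixture
def binding_model():
    """A + B <-> AB with kf = 1 /uM/s, kr = 1 /s (analytic equilibrium)."""
    m = NetworkModel(name="binding")
    m.species = [
        SpeciesDef("A", initial_concentration=1.0),
        SpeciesDef("B", initial_concentration=1.0),
        SpeciesDef("AB", initial_concentration=0.0),
    ]
    m.reactions = [MassActionReaction("bind", [("A", 1), ("B", 1)], [("AB", 1)], 1.0, 1.0)]
    return m


@pytest.fixture
def decay_model():
    """First-order decay A -> 0 at the rate of the CaMKII deactivation fixture."""
    m = NetworkModel(name="decay")
    m.species = [SpeciesDef("A", initial_concentration=2.0)]
    m.reactions = [MassActionReaction("decay", [("A", 1)], [], 0.166)]
    return m


@pytest.fixture(scope="session")
def wt_model():
    from msnsig.model import build_model

    return build_model("WT")


@pytest.fixture(scope="session")
def wt_basal(wt_model):
    from msnsig.model import basal_state

    return basal_state(wt_model)


def rng(seed=0):
    return np.random.default_rng(seed)
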