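import numpy as np
import pytest

import fvmapk as fv
from fvmapk.simulate import StimulusProtocol

#: coarser integration settings for tests that only need metric-level
#: accuracy; production defaults are exercised by the convergence test
FAST = dict(rtol=1e-6, atol=1e-3)


@pytest.fixture(scope="session")
def main_model():
    return fv.build_main_network()


@pytest.fixture(scope="session")
def hep_model(main_model):
    return fv.build_heparin_extension(main_model)


@pytest.fixture(scope="session")
def ensemble():
    return fv.load_best_fit_ensemble()


@pytest.fixture(scope="session")
def fgf_trajectory(main_model):
    """Baseline 0.5 nM FGF trajectory at production tolerances."""
    return fv.simulate(main_model, None, StimulusProtocol(fgf_nM=0.5))


@pytest.fixture(scope="session")
def vegf_trajectory(main_model):
    return fv.simulate(main_model, None, StimulusProtocol(vegf_nM=0.5))


@pytest.fixture(scope="session")
def toy_network():
    """A <-> B with kf = kr = 1, A0 = 2: analytic A(t) = 1 + exp(-2t)."""
    from fvmapk.network import ReactionNetwork, Reaction, Species

    net = ReactionNetwork(
        species=[Species("A", initial_amount=2.0), Species("B")],
        reactions=[Reaction("R1", [("A", 1)], [("B", 1)], 1.0, 1.0)],
    )
    net.validate()
    return net
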