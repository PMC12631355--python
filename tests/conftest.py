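import numpy as np
import pytest

from lewmd import SimulationProtocol, build_box, get_model


@pytest.fixture(scope="session")
def small_box_3site():
    """27 FBA_mem molecules on a lattice at ambient density."""
    return build_box(get_model("FBA_mem"), 27, target_density=0.994, seed=7)


@pytest.fixture(scope="session")
def small_box_4site():
    return build_box(get_model("T4F_mem"), 27, target_density=0.994, seed=7)


@pytest.fixture()
def tiny_protocol():
    """Protocol compatible with 27-molecule boxes (half-edge ~0.47 nm)."""
    return SimulationProtocol(cutoff=0.36, skin=0.08, n_steps=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
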