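import numpy as np
import pytest

from oncolysis import CellLineTruth, SimulationDesign


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def small_design():
    """Compact observation design for fast simulation tests."""
    return SimulationDesign(
        moi_grid=(0.0, 0.01, 1.0), t_end=60.0, dt=2.0, n_wells=3, n_repeats=3, seed=7
    )


@pytest.fixture
def susceptible_truth():
    return CellLineTruth(name="HOT", g=0.05, K=95, C0=8, kmax=0.08, m50=0.05)


@pytest.fixture
def null_truth():
    """A true null line: no MOI effect by construction."""
    return CellLineTruth(name="NULL", g=0.05, K=95, C0=8, kmax=0.0)
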