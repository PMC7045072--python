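import numpy as np
import pytest

from unfoldmsm.langevin import LangevinParams
from unfoldmsm.potentials import PotentialSpec, default_bead_pairs


@pytest.fixture
def double_well():
    return PotentialSpec("double_well_1d", barrier_height=4.0)


@pytest.fixture
def tilted_well():
    return PotentialSpec("tilted_double_well_1d", barrier_height=5.0,
                         asymmetry=2.0)


@pytest.fixture
def bead_chain():
    return PotentialSpec("bead_chain", barrier_height=5.0, asymmetry=2.0,
                         n_beads=6, bond_stiffness=30.0,
                         native_pair_list=default_bead_pairs(6),
                         contact_cutoff=1.1)


@pytest.fixture
def short_params():
    return LangevinParams(timestep=0.004, friction=1.0, temperature=1.0,
                          n_steps=2000, save_stride=10, seed=42)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
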