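import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

import confdyn as cd


@pytest.fixture(scope="session")
def helix12():
    return cd.build_ideal_helix(12)


@pytest.fixture(scope="session")
def helix30():
    return cd.build_ideal_helix(30)


@pytest.fixture(scope="session")
def toy_pair_spec():
    return cd.TwoStateToySpec()


@pytest.fixture(scope="session")
def toy_pair(toy_pair_spec):
    return cd.build_two_state_pair(toy_pair_spec)


@pytest.fixture(scope="session")
def delta_rmsd_spec(toy_pair, toy_pair_spec):
    state_a, state_b = toy_pair
    n_core = toy_pair_spec.n_core
    return cd.DeltaRmsdSpec(
        ref_agonistic=state_a,
        ref_antagonistic=state_b,
        fit_selection=cd.AtomSelection.backbone(1, n_core),
        calc_selection=cd.AtomSelection.ca(n_core + 1, toy_pair_spec.chain_length),
    )


@pytest.fixture(scope="session")
def double_well():
    return cd.double_well_potential(6.5, 3.0)
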