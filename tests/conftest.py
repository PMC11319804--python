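import numpy as np
import pytest

import aerodep as ad
from aerodep.tree import TreeParams

# small, fast geometry: terminals at generation 5 (32 outlets)
SMALL_PARAMS = TreeParams(diameter_ratio=0.6, length_ratio=0.6)


@pytest.fixture(scope="session")
def small_tree():
    return ad.generate_airway_tree(SMALL_PARAMS)


@pytest.fixture(scope="session")
def small_patient():
    return ad.make_patient(tree_params=SMALL_PARAMS, seed=0)


@pytest.fixture(scope="session")
def small_flow(small_patient):
    fr = ad.lobar_fractions(small_patient.volumes)
    outlets = ad.outlet_flow_profiles(small_patient.tree, fr,
                                      small_patient.pattern)
    return ad.solve_branch_flows(small_patient.tree, outlets)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
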