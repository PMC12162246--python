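import numpy as np
import pytest

from myoflow import (ContractileParams, PassiveParams, WallGeometry,
                     default_contractile_params, default_passive_params,
                     default_signalling_params, myograph_geometry)


@pytest.fixture(scope="session")
def sig_params():
    return default_signalling_params()


@pytest.fixture(scope="session")
def passive():
    return default_passive_params()


@pytest.fixture(scope="session")
def contractile():
    return default_contractile_params()


@pytest.fixture(scope="session")
def geom():
    """Default cannulated-vessel geometry (135 um load-free outer
    diameter, h_w = 0.25)."""
    return myograph_geometry()


@pytest.fixture(scope="session")
def mca_tree():
    from myoflow import default_mca_tree
    return default_mca_tree()
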