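import numpy as np
import pytest

from nosegc.flow import solve_flow
from nosegc.nose import build_nose, calibrate_to_morphometry, elongated_tube_variant, mouse_spec, rat_spec
from nosegc.odorants import MucosaSpec, default_odorants
from nosegc.pipeline import ML_MIN_TO_M3_S


@pytest.fixture(scope="session")
def mucosa():
    return MucosaSpec()


@pytest.fixture(scope="session")
def odorant_panel():
    return default_odorants()


@pytest.fixture(scope="session")
def mouse_network():
    spec = mouse_spec()
    return calibrate_to_morphometry(
        build_nose(spec), spec.target_surface_area, spec.target_volume
    )


@pytest.fixture(scope="session")
def mouse_flow(mouse_network):
    return solve_flow(mouse_network, 25.0 * ML_MIN_TO_M3_S, mouse_spec().dm_flow_fraction)


@pytest.fixture(scope="session")
def mouse_tube(mouse_network):
    return elongated_tube_variant(mouse_network)


@pytest.fixture(scope="session")
def mouse_tube_flow(mouse_tube):
    return solve_flow(mouse_tube, 25.0 * ML_MIN_TO_M3_S, mouse_spec().dm_flow_fraction)


@pytest.fixture(scope="session")
def rat_network():
    spec = rat_spec()
    return calibrate_to_morphometry(
        build_nose(spec), spec.target_surface_area, spec.target_volume
    )


@pytest.fixture(scope="session")
def rat_flow(rat_network):
    return solve_flow(rat_network, 200.0 * ML_MIN_TO_M3_S, rat_spec().dm_flow_fraction)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240608)
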