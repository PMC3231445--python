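import pytest
from hypothesis import HealthCheck, settings

import gasbiosense as gb

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def scenario():
    """The reference methanethiol / cytochrome-c scenario."""
    return gb.preset("methanethiol_cytc")


@pytest.fixture(scope="session")
def analyte(scenario):
    return scenario.analyte


@pytest.fixture(scope="session")
def sensor(scenario):
    return scenario.sensor


@pytest.fixture(scope="session")
def medium(scenario):
    return scenario.medium


@pytest.fixture(scope="session")
def gas(scenario):
    return scenario.gas


@pytest.fixture(scope="session")
def k_ref(scenario):
    """Literature second-order rate constant, 2.8e-3 uM^-1 s^-1."""
    return scenario.rate_constant


@pytest.fixture(scope="session")
def diffusion_scenario(analyte, sensor):
    return gb.DiffusionScenario(
        c0=gb.Quantity(39, "uM"),
        D=analyte.diffusion_coefficient,
        layer_depth=sensor.total_liquid_depth,
    )


@pytest.fixture(scope="session")
def optics(sensor):
    return gb.OpticalParams(
        epsilon=sensor.effective_delta_epsilon,
        path_length=sensor.sensing_layer_thickness,
    )
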