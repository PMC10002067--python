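import numpy as np
import pytest

import commutair as ca


@pytest.fixture(scope="session")
def config():
    return ca.load_config()


@pytest.fixture(scope="session")
def factor_set(config):
    return ca.EmissionFactorSet(config.emission_factors)


@pytest.fixture(scope="session")
def bus_trips():
    return ca.trips_from_frame(ca.load_bus_trip_table())


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_colocation(seed=0, duration_h=48.0, kappa=0.4, gain=1.0,
                    noise_relative=0.0, noise_sd=0.0, step_s=60.0):
    """Ambient field + confounded sensor readings with independent noise seed."""
    ambient = ca.simulate_ambient(
        ca.AmbientScenario(duration_h=duration_h, step_s=step_s, seed=seed)
    )
    response = ca.SensorResponseModel(
        gain=gain, noise_relative=noise_relative, noise_sd=noise_sd, kappa_true=kappa
    )
    sensor = ca.simulate_sensor(
        ambient["pm25"].to_numpy(), ambient["rh"].to_numpy(), response, seed=seed + 10_000
    )
    return ambient, sensor
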