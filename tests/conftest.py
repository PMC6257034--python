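import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import mangosoft as ms

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=40,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def keitt() -> ms.KineticParams:
    return ms.cultivar_kinetics("Keitt")


@pytest.fixture(scope="session")
def kent() -> ms.KineticParams:
    return ms.cultivar_kinetics("Kent")


def make_batch(batch_id="b1", n_fruit=10, f0_mean=60.0, f0_sd=8.0,
               eth_true=1.5, f_fix_true=12.7, temp_c=20.0, duration=16.0,
               noise_sd=1.0, kinetics=None, **kw) -> ms.BatchDesign:
    """Small constant-temperature batch design used across the suite."""
    return ms.BatchDesign(
        batch_id=batch_id, n_fruit=n_fruit, f0_mean=f0_mean, f0_sd=f0_sd,
        eth_true=eth_true, f_fix_true=f_fix_true,
        scenario=ms.TemperatureScenario.constant(duration, temp_c),
        measurement_times=np.arange(0.0, duration + 0.5, 2.0),
        kinetics=kinetics or ms.cultivar_kinetics("Keitt"),
        noise_sd=noise_sd, **kw)
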