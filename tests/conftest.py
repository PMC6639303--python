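import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import pmrkit as pk

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def er_threshold() -> float:
    """Noise-free texture decision threshold at default ER parameters."""
    return pk.calibrate_threshold()


@pytest.fixture()
def influx_pair():
    """A noise-free influx stack with ground truth and ROI."""
    model = pk.InfluxModel(noise_sd=0.0, photon_scale=0.0)
    stack, truth, roi = pk.generate_influx_stack(model, seed=11)
    return model, stack, truth, roi


@pytest.fixture()
def dff_of():
    def _convert(trace):
        return pk.to_delta_f_over_f(trace)

    return _convert


def assert_traces_close(a: np.ndarray, b: np.ndarray, tol: float) -> None:
    __tracebackhide__ = True
    err = np.max(np.abs(np.asarray(a) - np.asarray(b)))
    assert err <= tol, f"max abs deviation {err:.3g} exceeds {tol:.3g}"
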