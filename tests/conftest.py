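import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import dissipycle as dc

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def dz_params():
    return dc.default_params("dnazyme_exoIII")


@pytest.fixture(scope="session")
def dz_condition():
    return dc.default_condition("dnazyme_exoIII", condition_id="ref")


@pytest.fixture(scope="session")
def dz_network(dz_params, dz_condition):
    return dc.build_network(dz_params, dz_condition)


@pytest.fixture(scope="session")
def dz_single_dose(dz_condition):
    return (dc.DoseEvent(time=15.0, species="Fuel", amount=dz_condition.eq_to_uM(1)),)


@pytest.fixture(scope="session")
def dz_clean_cycle(dz_params, dz_condition, dz_single_dose):
    """Noiseless canonical single-cycle fluorescence trace (1 eq fuel)."""
    _, clean, trace = dc.generate_trace(
        dz_condition, dz_params, dz_single_dose, dc.NoiseModel(sigma=0.0),
        seed=0, t_end=150.0,
    )
    return clean, trace


def piecewise_linear_signal(t_d=15.0, slope=1.0, t_break=40.0, t_end=80.0,
                            dt=0.5, plateau_slope=0.0, baseline=0.0):
    """Exact two-segment trace: flat, linear rise from t_d, plateau after t_break."""
    t = np.arange(0.0, t_end + dt / 2, dt)
    v = np.full_like(t, baseline)
    rise = (t >= t_d) & (t < t_break)
    v[rise] = baseline + slope * (t[rise] - t_d)
    level = baseline + slope * (t_break - t_d)
    after = t >= t_break
    v[after] = level + plateau_slope * (t[after] - t_break)
    return dc.SignalTrace(channel="fluor520", time=t, values=v)
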