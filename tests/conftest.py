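import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from tomosync.breathing import BreathingParameters, generate_trace

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")

# Table-2-style motion parameters (A_Y, A_Z, A_X, period s, phi_Z cycle
# fraction, delivery time s) for the 13 subject cases
SUBJECT_CASES = {
    "Lung 1": (16, 10, 6, 5, 0.20, 126),
    "Lung 2": (5, 10, 9, 5, -0.10, 677),
    "Lung 3": (7, 14, 13, 5, -0.20, 694),
    "Lung 4": (12, 13, 13, 5, 0.0, 536),
    "Lung 5": (10, 6, 2, 5, 0.0, 252),
    "Liver 1": (9, 2, 1, 3, -0.50, 462),
    "Liver 2": (11, 14, 5, 4, -0.60, 253),
    "Liver 3": (16, 5, 1, 4, 0.10, 556),
    "Liver 4": (18, 16, 6, 3, 0.0, 568),
    "Pancreas 1": (13, 3, 1, 3, 0.20, 287),
    "Pancreas 2": (14, 11, 5, 5, -0.50, 289),
    "Pancreas 3": (14, 3, 1, 4, -0.10, 208),
    "Pancreas 4": (10, 6, 6, 4, -0.20, 246),
}


def case_breathing_parameters(name, seed=0, duration=None, **overrides):
    ay, az, ax, period, pz, delivery_s = SUBJECT_CASES[name]
    kw = dict(mean_amplitude_x=ax, mean_amplitude_y=ay, mean_amplitude_z=az,
              mean_period=period, phase_shift_z=pz,
              duration=duration if duration is not None else delivery_s + 15,
              seed=seed)
    kw.update(overrides)
    return BreathingParameters(**kw)


@pytest.fixture
def lung4_params():
    return case_breathing_parameters("Lung 4", seed=11, duration=120.0,
                                     drift_amplitude=0.0)


@pytest.fixture
def lung4_trace(lung4_params):
    return generate_trace(lung4_params)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
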