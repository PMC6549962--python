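import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from icbsim import CheckpointBlockadeModel, PatientParameters, SimulationSettings

settings.register_profile(
    "ci", deadline=None, max_examples=25, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def baseline_model() -> CheckpointBlockadeModel:
    """Baseline virtual patient: 30 mm, antigen 0.7, PD-L1 25%, 75 kg."""
    return CheckpointBlockadeModel(PatientParameters())


@pytest.fixture(scope="session")
def baseline_steady_state(baseline_model):
    """Drug-free pre-treatment steady state of the baseline patient
    (computed once per session; treated as read-only)."""
    return baseline_model.steady_state()


@pytest.fixture(scope="session")
def batch_settings() -> SimulationSettings:
    """Moderate-accuracy settings used for multi-simulation suites."""
    return SimulationSettings(rel_tol=1e-6, abs_tol=1e-8,
                              ss_tol=1e-3, ss_max_days=400.0)


def make_trajectory(t, diameter):
    """Synthetic diameter-only trajectory for response-analysis tests."""
    from icbsim.engine import Trajectory

    t = np.asarray(t, dtype=float)
    d = np.asarray(diameter, dtype=float)
    z = np.zeros_like(t)
    return Trajectory(t=t, diameter=d, teff_total=z, mapc_ln=z, serum={})
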