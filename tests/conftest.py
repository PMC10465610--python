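"""Shared fixtures.  Expensive simulations are session-scoped and reused."""

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, deadline=None)
settings.load_profile("ci")

from rodenergy import (
    StimulusProtocol, breakdown_from_components, dark_state_vector,
    default_parameters, full_derivative, integrate,
)
from rodenergy.protocols import FIG_FLASH_INTENSITIES, run_flash_family


@pytest.fixture(scope="session")
def params():
    return default_parameters()


@pytest.fixture(scope="session")
def dark_vector(params):
    return dark_state_vector(params)


@pytest.fixture(scope="session")
def dark_eval(params, dark_vector):
    """(derivative, breakdown, aux) at the dark operating point."""
    dy, comps, aux = full_derivative(dark_vector, params, 0.0)
    return dy, breakdown_from_components(comps), aux


@pytest.fixture(scope="session")
def light_run(params, dark_vector):
    """5 s of saturating constant light (4630 photons um^-2 s^-1)."""
    proto = StimulusProtocol("step", 4630.0, onset=0.0, duration=5.0)
    return integrate(dark_vector, proto, params, dt=2e-5, t_end=5.0, stride=500)


@pytest.fixture(scope="session")
def flash_family(params):
    """Flash intensity-response family at the published intensities."""
    series, summary = run_flash_family(params, dt=2e-5)
    return series, summary


@pytest.fixture(scope="session")
def light_series(params, dark_vector):
    """End-of-step ledger snapshots for the 5-s constant-light series."""
    rows = []
    for j in FIG_FLASH_INTENSITIES:
        proto = StimulusProtocol("step", j, onset=0.0, duration=5.0)
        s = integrate(dark_vector, proto, params, dt=2e-5, t_end=5.0, stride=5000)
        rows.append((j, s.ledger(len(s.t) - 1)))
    return rows


@pytest.fixture(scope="session")
def recovery_run(params, dark_vector):
    """Saturating 20-ms flash followed by 250 s of darkness."""
    proto = StimulusProtocol("flash", 4630.0, onset=0.5, duration=0.02)
    return integrate(dark_vector, proto, params, dt=5e-5, t_end=250.0, stride=5000)


def rel_err(value, expected):
    return abs(value - expected) / abs(expected)
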