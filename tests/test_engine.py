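"""Engine assembly, Euler integration, dark steady state."""

import numpy as np
import pytest

from rodenergy import (
    IntegrationError, StimulusProtocol, dark_state_vector,
    find_dark_steady_state, full_derivative, integrate,
)
from rodenergy.engine import CellState, breakdown_from_components, steady_state_residual


def test_dark_point_is_fixed_point(params, dark_vector, dark_eval):
    dy, b, _ = dark_eval
    assert steady_state_residual(dark_vector, params) < 1e-10
    assert abs(b.i_all) < 1e-10


def test_dvm_consistent_with_breakdown(params):
    """dVm/dt equals -(sum of the emitted components)/C_m at any state."""
    y = dark_state_vector(params)
    y[0] = -55.0
    y[1] = 8.0
    dy, comps, _ = full_derivative(y, params, 500.0)
    b = breakdown_from_components(comps)
    assert dy[0] == pytest.approx(-b.i_all / params.c_m * 1e3, rel=1e-12)


def test_decoupling_of_charge_and_species(params):
    """Equal and opposite per-ion fluxes leave Vm still while pools drift."""
    y = dark_state_vector(params)
    dy, comps, _ = full_derivative(y, params, 0.0)
    # at the calibrated dark point I_All = 0 yet individual pathway fluxes are large
    b = breakdown_from_components(comps)
    assert abs(b.i_all) < 1e-10
    assert abs(b.component("I_NaK", "Na")) > 10.0


def test_nonfinite_state_names_term(params):
    y = dark_state_vector(params)
    y[2] = np.nan
    with pytest.raises(IntegrationError):
        full_derivative(y, params, 0.0)


def test_find_dark_steady_state(params):
    """Residual below 1e-8, |I_All| < 1e-6 pA, persists under integration."""
    state = find_dark_steady_state(params)
    y = state.vector()
    _, comps, _ = full_derivative(y, params, 0.0)
    assert abs(sum(comps)) < 1e-6
    s = integrate(y, StimulusProtocol("dark"), params, dt=5e-5, t_end=10.0, stride=2000)
    assert np.max(np.abs(s.vm - state.vm)) < 0.01
    rel = np.abs(s.states[-1] - y) / np.maximum(np.abs(y), 1e-9)
    assert rel.max() < 1e-4  # concentrations move < 0.01%


def test_cellstate_round_trip(params, dark_vector):
    state = CellState.from_vector(dark_vector, t=1.5)
    assert np.allclose(state.vector(), dark_vector)
    with pytest.raises(ValueError):
        CellState.from_vector(np.r_[200.0, dark_vector[1:]])


def test_instability_detected(params):
    y = dark_state_vector(params)
    bad = params
    # a huge step makes Euler blow up through the Vm sanity window
    with pytest.raises(IntegrationError):
        integrate(y * 1.05, StimulusProtocol("step", 4630.0, 0.0, 1.0), bad,
                  dt=5e-3, t_end=1.0)


def test_dt_halving_convergence(params, dark_vector):
    """Halving the Euler step changes the Vm trace by < 0.1% (sup-norm)."""
    proto = StimulusProtocol("flash", 444.0, onset=0.1, duration=0.02)
    a = integrate(dark_vector, proto, params, dt=2e-5, t_end=1.0, stride=50)
    b = integrate(dark_vector, proto, params, dt=1e-5, t_end=1.0, stride=100)
    assert np.max(np.abs(a.vm - b.vm)) / np.max(np.abs(b.vm)) < 1e-3


def test_saturating_flash_hyperpolarizes(params, flash_family):
    series, _ = flash_family
    bright = series[4630.0]
    assert bright.vm.min() < -55.0


def test_light_plateau_window(light_run):
    """5-s saturating light settles between -45 and -50 mV."""
    assert -50.0 <= light_run.vm[-1] <= -45.0
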