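"""Two-compartment Ca2+ balance, buffering and diffusion."""

import math

import pytest

from rodenergy import (
    BufferSpec, CompartmentGeometry, buffer_kinetics,
    ca_is_derivative, ca_os_derivative, j_dif,
)
from rodenergy.driving import CONSTANTS

GEOM = CompartmentGeometry(v_os=2e-14, v_is=8e-14)


class TestCompartmentDerivatives:
    def test_all_zero(self):
        assert ca_os_derivative(0, 0, 0, 0, 0, GEOM) == 0.0
        assert ca_is_derivative(0, 0, 0, 0, 0, 0, GEOM) == 0.0

    def test_inward_current_raises_concentration(self):
        assert ca_os_derivative(-1.0, 0, 0, 0, 0, GEOM) > 0
        assert ca_is_derivative(-1.0, 0, 0, 0, 0, 0, GEOM) > 0

    def test_exchanger_net_current_enters_with_factor_two(self):
        """-2*I_NCKX converts the one-charge-per-cycle net current into its
        two-charge Ca component: a forward cycle (I < 0) removes Ca."""
        d = ca_os_derivative(0.0, -1.0, 0.0, 0.0, 0.0, GEOM)
        direct = -(2.0 * 1.0) * 1e-6 / (2 * CONSTANTS.F * GEOM.v_os)
        assert d == pytest.approx(direct, rel=1e-12)

    def test_held_flux_integrates_linearly(self):
        """Constant current for dt changes [Ca] by I/(2 F V) * dt."""
        i = -0.5  # pA inward
        rate = ca_os_derivative(i, 0, 0, 0, 0, GEOM)
        expected = -i * 1e-6 / (2 * CONSTANTS.F * GEOM.v_os)
        assert rate == pytest.approx(expected, rel=1e-12)
        assert rate * 0.01 == pytest.approx(expected * 0.01, rel=1e-12)

    def test_diffusion_conserves_moles(self):
        """J_dif moves moles from OS to IS without creating any."""
        j = j_dif(0.3, 0.1, 2e6)
        d_os = ca_os_derivative(0, 0, 0, 0, j, GEOM)
        d_is = ca_is_derivative(0, 0, 0, 0, 0, j, GEOM)
        assert d_os < 0 < d_is
        total = d_os * GEOM.v_os + d_is * GEOM.v_is
        assert abs(total) < 1e-20


class TestBuffer:
    BUF = BufferSpec(b_tot=50.0, k_d=2.0, k_on=20.0)

    def test_zero_and_equilibrium(self):
        assert buffer_kinetics(0.0, 0.0, self.BUF) == 0.0
        bound_eq = self.BUF.equilibrium_bound(0.3)
        assert buffer_kinetics(0.3, bound_eq, self.BUF) == pytest.approx(0.0, abs=1e-12)

    def test_relaxation_toward_new_equilibrium(self):
        """After a step in free Ca, bound Ca relaxes exponentially with rate
        k_on (B_tot - b) ~ k_on B_free + k_off (linearized)."""
        free = 0.6
        b = self.BUF.equilibrium_bound(0.3)
        b_eq = self.BUF.equilibrium_bound(free)
        dt, t = 1e-5, 0.0
        rate0 = buffer_kinetics(free, b, self.BUF)
        assert rate0 > 0
        while t < 0.5:
            b += dt * buffer_kinetics(free, b, self.BUF)
            t += dt
        assert b == pytest.approx(b_eq, rel=1e-4)

    def test_capacity_enforced(self):
        with pytest.raises(ValueError):
            buffer_kinetics(0.3, 51.0, self.BUF)


def test_j_dif_antisymmetric_and_zero_at_equal():
    assert j_dif(0.2, 0.2, 2e6) == 0.0
    assert j_dif(0.3, 0.1, 2e6) == -j_dif(0.1, 0.3, 2e6)


def test_two_box_relaxation_conserves_and_equalizes():
    """With membrane fluxes frozen, the compartments relax to a common
    concentration that conserves total moles."""
    ca_os, ca_is = 0.5, 0.1
    g = 2e6  # ions/s per uM
    dt = 1e-4
    n_os = CONSTANTS.N_A * GEOM.v_os * 1e-6  # ions per uM
    n_is = CONSTANTS.N_A * GEOM.v_is * 1e-6
    total0 = ca_os * n_os + ca_is * n_is
    for _ in range(200000):
        j = j_dif(ca_os, ca_is, g) * CONSTANTS.N_A  # ions/s
        ca_os -= dt * j / n_os
        ca_is += dt * j / n_is
    assert ca_os == pytest.approx(ca_is, rel=1e-6)
    assert ca_os * n_os + ca_is * n_is == pytest.approx(total0, rel=1e-9)
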