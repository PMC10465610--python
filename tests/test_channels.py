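"""Gated channel currents and first-order gating kinetics."""

import math

import pytest

from rodenergy import (
    ChannelSpec, GateSpec, IonSpec,
    cng_open_fraction, gating_step, multi_ion_current, nernst_potential,
    single_ion_current,
)

NA = IonSpec("Na", 1, 145.0, 10.0)
K = IonSpec("K", 1, 5.0, 140.0)
CA = IonSpec("Ca", 2, 2.0, 3e-4)


def _gate(v_half=-30.0, slope=8.0, tau=0.02, m=1):
    return GateSpec(
        steady_state=lambda v: 1.0 / (1.0 + math.exp((v_half - v) / slope)),
        time_constant=lambda v: tau,
        exponent=m,
    )


class TestGating:
    def test_fixed_point(self):
        g = _gate()
        m0 = g.steady_state(-40.0)
        assert gating_step(m0, g, -40.0, 0.004) == pytest.approx(m0, rel=1e-12)

    def test_voltage_clamp_matches_exponential_relaxation(self):
        """Long voltage clamp follows m(t) = m_inf + (m0 - m_inf) e^(-t/tau)."""
        g = _gate(tau=0.02)
        vm, dt = -20.0, 1e-5
        m_inf = g.steady_state(vm)
        m = 0.0
        n = int(0.2 / dt)  # 10 time constants
        for _ in range(n):
            m = gating_step(m, g, vm, dt)
        exact = m_inf + (0.0 - m_inf) * math.exp(-0.2 / 0.02)
        assert m == pytest.approx(exact, abs=1e-6)
        assert m == pytest.approx(m_inf, abs=1e-4)

    def test_clamped_to_unit_interval_and_dt_validated(self):
        g = _gate(tau=1e-4)
        assert 0.0 <= gating_step(0.99, g, 60.0, 0.01) <= 1.0
        with pytest.raises(ValueError):
            gating_step(0.5, g, -40.0, 0.0)


class TestSingleIon:
    def test_reference_value(self):
        """I = g m^M h (Vm - E) with g=0.5, m=0.4, Vm=-40, E=-74 -> 6.8 pA."""
        spec = ChannelSpec("I_Kv", 0.5, ["K"])
        out = single_ion_current(spec, 0.4, 1.0, -40.0, -74.0)
        assert out.total == pytest.approx(6.8, rel=1e-12)
        assert out.per_ion["K"] == out.total

    @pytest.mark.parametrize("g,m,vm,e", [(0.0, 0.7, -40.0, -74.0), (0.5, 0.7, -74.0, -74.0)])
    def test_zero_cases(self, g, m, vm, e):
        spec = ChannelSpec("I_Kv", g, ["K"])
        assert single_ion_current(spec, m, 1.0, vm, e).total == 0.0

    def test_multi_ion_spec_rejected(self):
        spec = ChannelSpec("I_CNG", 1.0, ["Na", "K"])
        with pytest.raises(ValueError):
            single_ion_current(spec, 0.5, 1.0, -40.0, -74.0)


class TestMultiIon:
    def test_all_gates_closed(self):
        spec = ChannelSpec("I_CNG", 2.0, ["Na", "K", "Ca"], {"Ca": 5.0, "K": 1.0})
        out = multi_ion_current(spec, 0.0, 1.0, -40.0, [NA, K, CA])
        assert all(v == 0.0 for v in out.per_ion.values())

    def test_component_vanishes_at_its_nernst_potential(self):
        spec = ChannelSpec("I_h", 1.5, ["Na", "K"], {"Na": 0.33, "K": 1.0})
        e_k = nernst_potential(K)
        out = multi_ion_current(spec, 0.5, 1.0, e_k, [NA, K])
        assert abs(out.per_ion["K"]) < 1e-10
        assert out.per_ion["Na"] != 0.0

    def test_total_is_sum_of_components(self):
        spec = ChannelSpec("I_CNG", 2.0, ["Na", "K", "Ca"], {"Ca": 5.0, "K": 1.0})
        out = multi_ion_current(spec, 0.3, 1.0, -36.0, [NA, K, CA])
        assert out.total == pytest.approx(sum(out.per_ion.values()), abs=1e-12)


class TestCngOpenFraction:
    def test_zero_and_saturation(self):
        assert cng_open_fraction(0.0, 0.3) == 0.0
        assert cng_open_fraction(1e6, 0.3) == pytest.approx(1.0, abs=1e-6)

    def test_monotone_in_cgmp_and_decreasing_in_ca(self):
        vals = [cng_open_fraction(c, 0.3) for c in (0.5, 1, 2, 4, 8, 16)]
        assert vals == sorted(vals)
        assert cng_open_fraction(4.0, 1.0) < cng_open_fraction(4.0, 0.1)
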