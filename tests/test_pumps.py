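"""Pumps, exchangers, cotransporters and leaks: stoichiometry and saturation."""

import math

import pytest
from hypothesis import given, settings, strategies as st

from rodenergy import (
    IonSpec, LeakSet, cotransporter_fluxes, i_nak, i_nckx, i_ncx, i_pmca,
    leak_currents, nernst_potential,
)
from rodenergy.channels import boltzmann


def _ions(na_i=10.0, k_i=140.0, cl_i=30.0):
    return (
        IonSpec("Na", 1, 145.0, na_i),
        IonSpec("K", 1, 5.0, k_i),
        IonSpec("Cl", -1, 110.0, cl_i),
    )


@settings(deadline=None, max_examples=50)
@given(
    vm=st.floats(-110.0, 50.0),
    na_i=st.floats(0.5, 50.0),
    ca=st.floats(1e-4, 10.0),
)
def test_stoichiometric_identities_hold_everywhere(params, vm, na_i, ca):
    """NaK 3:2:(+1), NCKX 4:1:1:(-1), NCX 3:1:(-1) at any state; e = e_pa."""
    e = params.constants.e_pa
    na, k, _ = _ions(na_i)

    nak = i_nak(vm, na_i, params.k_o, params)
    assert nak.per_ion["Na"] == pytest.approx(3.0 * nak.rate * e, rel=1e-12)
    assert nak.per_ion["K"] == pytest.approx(-2.0 * nak.rate * e, rel=1e-12)
    assert nak.current == pytest.approx(nak.rate * e, rel=1e-9)

    nckx = i_nckx(vm, na, ca, k, params)
    assert nckx.per_ion["Na"] == pytest.approx(-4.0 * nckx.rate * e, rel=1e-12)
    assert nckx.per_ion["Ca"] == pytest.approx(2.0 * nckx.rate * e, rel=1e-12)
    assert nckx.per_ion["K"] == pytest.approx(nckx.rate * e, rel=1e-12)
    assert nckx.current == pytest.approx(-nckx.rate * e, rel=1e-9)

    ncx = i_ncx(vm, na, ca, params)
    assert ncx.per_ion["Na"] / ncx.per_ion["Ca"] == pytest.approx(-1.5, rel=1e-12)
    assert ncx.current == pytest.approx(-ncx.rate * e, rel=1e-9)


def test_zero_substrate_zero_flux(params):
    na, k, _ = _ions()
    assert i_nak(-36.2, 0.0, params.k_o, params).rate == 0.0
    assert i_pmca(0.0, params).rate == 0.0
    assert i_nckx(-36.2, na, 0.0, k, params).rate == 0.0
    assert i_ncx(-36.2, na, 0.0, params).rate == 0.0


def test_pmca_monotone_saturating(params):
    rates = [i_pmca(c, params).rate for c in (0.05, 0.1, 0.2, 0.4, 10.0)]
    assert rates == sorted(rates)
    assert rates[-1] < params.p_max_pmca


def test_nak_operating_points(params):
    """~80% of the saturated voltage factor at rest, ~65% below -55 mV."""
    fv_rest = boltzmann(params.dark.vm_dark, params.vhalf_nak, params.slope_nak)
    fv_hyp = boltzmann(-57.0, params.vhalf_nak, params.slope_nak)
    assert fv_rest == pytest.approx(0.80, abs=0.01)
    assert fv_hyp == pytest.approx(0.65, abs=0.02)


class TestCotransporters:
    def test_zero_net_charge(self, params):
        nkcc1, kcc2 = cotransporter_fluxes(-36.2, *_ions(), params)
        assert abs(sum(nkcc1.per_ion.values())) < 1e-12
        assert abs(sum(kcc2.per_ion.values())) < 1e-12

    def test_physiological_directions(self, params):
        """NKCC1 takes Cl- up; KCC2 extrudes it."""
        nkcc1, kcc2 = cotransporter_fluxes(-36.2, *_ions(), params)
        assert nkcc1.rate > 0 and nkcc1.per_ion["Cl"] > 0  # anion influx: outward current
        assert kcc2.rate > 0 and kcc2.per_ion["Cl"] < 0

    def test_equilibrium_and_scale_invariance(self, params):
        """Zero flux at the transported-product equilibrium, also after
        doubling every concentration."""
        # KCC2 equilibrium: K_i Cl_i = K_o Cl_o
        for scale in (1.0, 2.0):
            na = IonSpec("Na", 1, 145.0 * scale, 10.0 * scale)
            k = IonSpec("K", 1, 5.0 * scale, 50.0 * scale)
            cl = IonSpec("Cl", -1, 110.0 * scale, 11.0 * scale)  # 50*11 = 5*110
            _, kcc2 = cotransporter_fluxes(-36.2, na, k, cl, params)
            assert abs(kcc2.rate) < 1e-9 * params.u_kcc2
        # NKCC1 equilibrium: Na_o K_o Cl_o^2 = Na_i K_i Cl_i^2
        for scale in (1.0, 2.0):
            na = IonSpec("Na", 1, 145.0 * scale, 145.0 * scale)
            k = IonSpec("K", 1, 5.0 * scale, 5.0 * scale)
            cl = IonSpec("Cl", -1, 110.0 * scale, 110.0 * scale)
            nkcc1, _ = cotransporter_fluxes(-36.2, na, k, cl, params)
            assert abs(nkcc1.rate) < 1e-9 * params.u_nkcc1


def test_leaks_zero_when_conductance_zero_or_at_reversal(params):
    ions = _ions()
    ca_os = IonSpec("Ca", 2, 2.0, 3e-4)
    ca_is = IonSpec("Ca", 2, 2.0, 1e-4)
    zero = LeakSet(0.0, 0.0, 0.0, 0.0, 0.0)
    assert all(v == 0.0 for v in leak_currents(-36.2, *ions, ca_os, ca_is, zero).values())
    leaks = LeakSet(params.g_l_k, params.g_l_na, params.g_l_cl,
                    params.g_l_caos, params.g_l_cais)
    e_k = nernst_potential(ions[1])
    out = leak_currents(e_k, *ions, ca_os, ca_is, leaks)
    assert out["L_K"] == pytest.approx(0.0, abs=1e-12)
    assert out["L_Na"] != 0.0
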