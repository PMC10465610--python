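"""ATP accounting: stoichiometric conversion rules and influx attribution."""

import pytest

from rodenergy import (
    CurrentBreakdown, atp_rate_for_ca, atp_rate_for_na, compute_ledger,
    decompose_k_efflux, decompose_na_influx, total_atp,
)
from rodenergy.driving import CONSTANTS


def test_atp_for_na_reference_value():
    """1 mM/s into 1e-12 L at 3 Na+ per ATP -> 2.00738e8 molecules/s."""
    assert atp_rate_for_na(0.0, 1e-12) == 0.0
    assert atp_rate_for_na(1.0, 1e-12) == pytest.approx(2.00738025333e8, rel=1e-9)
    with pytest.raises(ValueError):
        atp_rate_for_na(-1.0, 1e-12)


def test_atp_for_ca_is_one_to_one():
    """1 uM/s into V_is litres -> N_A V_is 1e-6 molecules/s (1 ATP per Ca)."""
    v_is = 8e-14
    expected = CONSTANTS.N_A * v_is * 1e-6
    assert atp_rate_for_ca(1.0, v_is) == pytest.approx(expected, rel=1e-12)
    assert atp_rate_for_ca(0.0, v_is) == 0.0


def test_single_source_gets_full_share():
    e = CONSTANTS.e_pa
    b = CurrentBreakdown({"I_CNG": {"Na": -1e7 * e}, "I_h": {"Na": 0.0}})
    shares = decompose_na_influx(b)
    assert shares["I_CNG"] == pytest.approx(1.0)
    assert shares["I_h"] == 0.0


def test_zero_influx_returns_empty():
    b = CurrentBreakdown({"I_CNG": {"Na": 5.0}})  # outward only
    assert decompose_na_influx(b) == {}
    assert decompose_k_efflux(CurrentBreakdown({"I_Kv": {"K": -1.0}})) == {}


def test_shares_sum_to_one(dark_eval):
    _, b, _ = dark_eval
    na = decompose_na_influx(b)
    k = decompose_k_efflux(b)
    assert sum(na.values()) == pytest.approx(1.0, abs=1e-9)
    assert sum(k.values()) == pytest.approx(1.0, abs=1e-9)


def test_ledger_internal_consistency(params, dark_eval):
    """NaK total equals the sum over sources; total = NaK + PMCA + cascade;
    at steady state the influx-based rate equals the pump-actual rate."""
    _, b, aux = dark_eval
    led = compute_ledger(b, aux[3], params.v_is, aux[0], aux[1], aux[2],
                         params.constants)
    assert led.atp_nak_total == pytest.approx(sum(led.atp_nak_by_source.values()),
                                              rel=1e-9)
    assert total_atp(led) == pytest.approx(
        led.atp_nak_total + led.atp_pmca + led.atp_cascade, rel=1e-12
    )
    assert led.atp_nak_total == pytest.approx(led.atp_nak_pump, rel=1e-6)
    assert led.atp_pmca == pytest.approx(led.atp_pmca_pump, rel=1e-2)


def test_influx_rate_formula_matches_component_sum(params, dark_eval):
    """The mM/s-based ATP formula reproduces the per-component attribution."""
    _, b, aux = dark_eval
    led = compute_ledger(b, aux[3], params.v_is, aux[0], aux[1], aux[2],
                         params.constants)
    e = params.constants.e_pa
    influx_ions = sum(
        max(0.0, -b.component(n, "Na")) / e
        for n in ("I_CNG", "I_NCKX", "I_h", "I_CaL", "I_NCX", "J_NKCC1", "I_L_Na")
    )
    influx_mm = influx_ions / (params.constants.N_A * params.v_cell * 1e-3)
    assert atp_rate_for_na(influx_mm, params.v_cell) == pytest.approx(
        led.atp_nak_total, rel=1e-9
    )
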