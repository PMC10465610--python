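"""Validation harness: degenerate mini-models with independent oracles and
the quantitative regression suite tied to the published anchor values.

The two-current fixture reduces the cell to an ohmic K+ leak, a Na+ leak and
the Na/K pump.  Its steady state satisfies a small algebraic system that an
independent root solve (no time stepping) can produce, giving an oracle for
the full engine configured down to the same three pathways.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

from .engine import dark_state_vector, full_derivative, integrate
from .cascade import StimulusProtocol
from .ledger import decompose_k_efflux, decompose_na_influx
from .params import DarkTargets, ModelParameters, default_parameters

__all__ = ["MiniModel", "make_two_current_fixture", "run_regression_suite"]


@dataclass
class MiniModel:
    """Reduced model: K leak + Na leak + Na/K pump, plus its initial state."""

    params: ModelParameters
    y0: np.ndarray

    def closed_form_steady_state(self, y0=None) -> tuple[float, float, float]:
        """Steady (Vm, Na_i, K_i) from the algebraic balance equations.

        Solves dNa/dt = 0, dK/dt = 0 together with the trajectory invariant
        Q = Vm - gamma (Na + K) (the voltage is an exact linear functional of
        the transported charge), using a root finder on the algebraic system
        rather than time integration.
        """
        from scipy.optimize import root
        import math

        p = self.params
        c = p.constants
        e_pa = c.e_pa
        rtf_mv = c.R * c.T / c.F * 1e3
        gamma = c.F * p.v_cell * 1e12 / p.c_m  # mV per (mM Na + mM K)
        start = self.y0 if y0 is None else y0
        v0, na0, k0 = start[0], start[1], start[2]
        q0 = v0 - gamma * (na0 + k0)

        def pump_rate(v, na):
            fv = 1.0 / (1.0 + math.exp((p.vhalf_nak - v) / p.slope_nak))
            h_na = na**p.n_nak_na / (na**p.n_nak_na + p.km_nak_na**p.n_nak_na)
            h_k = p.k_o**p.n_nak_k / (p.k_o**p.n_nak_k + p.km_nak_k**p.n_nak_k)
            return p.i_max_nak / e_pa * fv * h_na * h_k

        def eqs(x):
            v, na, k = x
            e_na = rtf_mv * math.log(p.na_o / na)
            e_k = rtf_mv * math.log(p.k_o / k)
            r = pump_rate(v, na)
            f_na = 3.0 * r * e_pa + p.g_l_na * (v - e_na)  # net outward Na, pA
            f_k = -2.0 * r * e_pa + p.g_l_k * (v - e_k)
            return [f_na, f_k, (v - gamma * (na + k) - q0) / gamma]

        sol = root(eqs, [v0, na0, k0], method="hybr", tol=1e-14)
        if not sol.success:
            raise RuntimeError(f"mini-model oracle failed: {sol.message}")
        return tuple(sol.x)


def make_two_current_fixture(
    pump_atp: float = 1.0e7, na_i: float = 10.0, k_i: float = 140.0
) -> MiniModel:
    """Engine parameters with every pathway zeroed except L_K, L_Na and NaK.

    The pump runs at ``pump_atp`` cycles/s at the reference state; the two
    leak conductances are solved so the reference state is a fixed point
    (the same closure logic as the full calibration, in miniature).
    """
    base = default_parameters()
    c = base.constants
    e_pa = c.e_pa
    vm = -80.0  # reference potential, leak-dominated cell
    rtf_mv = c.R * c.T / c.F * 1e3
    import math

    e_na = rtf_mv * math.log(base.na_o / na_i)
    e_k = rtf_mv * math.log(base.k_o / k_i)
    fv = 1.0 / (1.0 + math.exp((base.vhalf_nak - vm) / base.slope_nak))
    h_na = na_i**base.n_nak_na / (na_i**base.n_nak_na + base.km_nak_na**base.n_nak_na)
    h_k = base.k_o**base.n_nak_k / (base.k_o**base.n_nak_k + base.km_nak_k**base.n_nak_k)
    i_max_nak = pump_atp * e_pa / (fv * h_na * h_k)
    g_l_na = 3.0 * pump_atp * e_pa / (e_na - vm)  # leak carries Na back in
    g_l_k = 2.0 * pump_atp * e_pa / (vm - e_k)  # leak carries K back out

    dark = dataclasses.replace(
        DarkTargets(), vm_dark=vm, na_i=na_i, k_i=k_i
    )
    p = dataclasses.replace(
        base,
        dark=dark,
        g_cng=0.0, g_h=0.0, g_cal=0.0, g_kv=0.0, g_kca=0.0, g_clca=0.0,
        i_max_nckx=0.0, p_max_pmca=0.0, r_max_ncx=0.0,
        u_nkcc1=0.0, u_kcc2=0.0,
        g_l_cl=0.0, g_l_caos=0.0, g_l_cais=0.0, g_dif=0.0,
        alpha_max=0.0, beta_dark=1.0, k_cyc=1.0,
        btot_os=0.0, btot_is=0.0,
        i_max_nak=i_max_nak, g_l_na=g_l_na, g_l_k=g_l_k,
    )
    y0 = dark_state_vector(p)
    y0[12:] = 0.0  # no cascade species
    return MiniModel(params=p, y0=y0)


# ----------------------------------------------------------------------
# regression suite
# ----------------------------------------------------------------------

def _entry(name, value, expected, rel_tol):
    dev = abs(value - expected) / abs(expected) if expected else abs(value)
    return {
        "target": name,
        "value": float(value),
        "expected": float(expected),
        "rel_deviation": float(dev),
        "rel_tolerance": float(rel_tol),
        "pass": bool(dev <= rel_tol),
    }


def run_regression_suite(
    p: ModelParameters | None = None,
    include_flash: bool = True,
    dt: float = 2e-5,
) -> dict:
    """Evaluate the published anchor values with their tolerance bands.

    Returns a deterministic, machine-readable report with the per-target
    relative deviation.  Tolerances: 10% for ATP magnitudes, shares and
    times (the source reports them as approximate), 1 mV for voltage
    landmarks expressed as window checks.
    """
    from .protocols import run_energy_budget, run_flash_family

    p = p or default_parameters()
    y0 = dark_state_vector(p)
    _, comps, aux = full_derivative(y0, p, 0.0)
    from .engine import breakdown_from_components
    b = breakdown_from_components(comps)
    from .ledger import compute_ledger
    led = compute_ledger(b, aux[3], p.v_is, aux[0], aux[1], aux[2], p.constants)
    na_sh = decompose_na_influx(b, p.constants)
    k_sh = decompose_k_efflux(b, p.constants)
    i_os = b.total("I_CNG") + b.total("I_NCKX")

    targets = [
        _entry("dark_total_atp", led.total, 7.0e7, 0.10),
        _entry("dark_nak_atp", led.atp_nak_total, 5.0e7, 0.10),
        _entry("dark_pmca_atp", led.atp_pmca, 2.0e7, 0.10),
        _entry("dark_os_current_pA", i_os, -15.0, 0.10),
        _entry("dark_cng_share_os", b.total("I_CNG") / i_os, 0.944, 0.10),
        _entry("dark_na_share_cng", na_sh["I_CNG"], 0.65, 0.10),
        _entry("dark_na_share_nckx", na_sh["I_NCKX"], 0.14, 0.10),
        _entry("dark_na_share_h", na_sh["I_h"], 0.20, 0.10),
        _entry("dark_k_share_kv", k_sh["I_Kv"], 0.495, 0.10),
        _entry("dark_k_share_cng", k_sh["I_CNG"], 0.209, 0.10),
        _entry("dark_k_share_h", k_sh["I_h"], 0.193, 0.10),
    ]

    budget = run_energy_budget(p, dt=dt)
    light = budget["light"]
    summ = budget["summary"]
    ih_share = light["atp_nak_by_source"].get("I_h", 0.0) / light["atp_total"]
    targets += [
        _entry("light_total_atp", light["atp_total"], 4.3e7, 0.10),
        _entry("light_total_over_dark", summ["total_light_over_dark"], 0.624, 0.10),
        _entry("light_ih_share_total", ih_share, 0.83, 0.10),
        _entry("light_na_atp_decrease", summ["na_atp_decrease_fraction"], 0.276, 0.10),
        _entry("light_ca_atp_decrease", summ["ca_atp_decrease_fraction"], 0.659, 0.10),
        _entry("light_pmca_atp", light["atp_pmca"], 6.3e6, 0.15),
        _entry("light_k_share_kv", light["k_efflux_shares"]["I_Kv"], 0.351, 0.15),
        _entry("light_k_share_h", light["k_efflux_shares"]["I_h"], 0.618, 0.10),
        _entry(
            "light_plateau_vm_window",
            1.0 if -50.0 <= light["vm_mV"] <= -45.0 else 0.0,
            1.0, 0.0,
        ),
    ]

    if include_flash:
        _, fam = run_flash_family(p, dt=dt)
        bright = fam["rows"][-1]
        targets += [
            _entry("flash_half_max_intensity", fam["half_max_intensity"], 43.5, 0.10),
            _entry("flash_time_to_peak_s", fam["time_to_peak_at_half_max_s"], 0.185, 0.10),
            _entry(
                "flash_saturating_hyperpol",
                1.0 if bright["vm_min_mV"] < -55.0 else 0.0,
                1.0, 0.0,
            ),
            _entry("flash_ih_peak_pA_per_pF", bright["ih_peak_pA_per_pF"], -3.9, 0.10),
            _entry("flash_ih_peak_time_s", bright["ih_peak_time_s"], 0.047, 0.10),
            _entry("flash_clca_peak_pA_per_pF", bright["clca_peak_pA_per_pF"], -0.4, 0.10),
            _entry("flash_clca_peak_time_s", bright["clca_peak_time_s"], 0.034, 0.10),
        ]

    return {
        "n_pass": sum(t["pass"] for t in targets),
        "n_total": len(targets),
        "targets": targets,
    }
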