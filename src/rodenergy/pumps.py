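"""Electrogenic pumps and exchangers, electroneutral cotransporters, leaks.

All carriers obey exact integer stoichiometry at every evaluation:

* NaK pump: 3 Na+ out, 2 K+ in, 1 ATP  -> net charge +1 out per cycle
* PMCA pump: 1 Ca2+ out, 1 ATP         -> net charge +2 out per cycle
* NCKX: 4 Na+ in, 1 Ca2+ + 1 K+ out    -> net charge +1 in per cycle
* NCX: 3 Na+ in, 1 Ca2+ out            -> net charge +1 in per cycle
* NKCC1: 1 Na+ + 1 K+ + 2 Cl- in, KCC2: 1 K+ + 1 Cl- out -> zero net charge

Functional forms are simplified saturating laws (Hill in the limiting
substrate, a Boltzmann voltage factor for the NaK pump) whose scales are set
by the dark-state calibration; cotransporters use thermodynamic log-ratio
flux laws that vanish at equilibrium of the transported species product and
are invariant under uniform scaling of all concentrations.

Per-ion components are expressed in charge-equivalent pA (z * e0 * ion flux,
outward positive) so that components from every pathway sum directly into the
membrane current and into d[ion]/dt bookkeeping.
"""

from __future__ import annotations

import math
from typing import NamedTuple

from .channels import boltzmann, hill
from .driving import CONSTANTS, IonSpec, PhysicalConstants, nernst_potential
from .params import ModelParameters

__all__ = [
    "PumpResult",
    "LeakSet",
    "i_nak",
    "i_pmca",
    "i_nckx",
    "i_ncx",
    "cotransporter_fluxes",
    "leak_currents",
]


class PumpResult(NamedTuple):
    """Net current (pA), per-ion charge components (pA) and cycle rate (1/s)."""

    current: float
    per_ion: dict
    rate: float


class LeakSet(NamedTuple):
    g_l_k: float
    g_l_na: float
    g_l_cl: float
    g_l_caos: float
    g_l_cais: float


def i_nak(vm: float, na_i: float, k_o: float, p: ModelParameters) -> PumpResult:
    """Na/K-ATPase: Boltzmann voltage factor times substrate saturation.

    The cycle rate equals the ATP hydrolysis rate; per-ion fluxes are exactly
    3 Na+ out : 2 K+ in per cycle, net charge +1 out.
    """
    if na_i < 0 or k_o < 0:
        raise ValueError("concentrations must be non-negative")
    e0 = p.constants.e_pa
    fv = boltzmann(vm, p.vhalf_nak, p.slope_nak)
    rate = (
        p.i_max_nak
        / e0
        * fv
        * hill(na_i, p.km_nak_na, p.n_nak_na)
        * hill(k_o, p.km_nak_k, p.n_nak_k)
    )
    per_ion = {"Na": 3.0 * rate * e0, "K": -2.0 * rate * e0}
    return PumpResult(per_ion["Na"] + per_ion["K"], per_ion, rate)


def i_pmca(ca_is: float, p: ModelParameters) -> PumpResult:
    """Plasma-membrane Ca-ATPase: 1 Ca2+ out per ATP, Hill saturation in Ca."""
    if ca_is < 0:
        raise ValueError("Ca concentration must be non-negative")
    e0 = p.constants.e_pa
    rate = p.p_max_pmca * hill(ca_is, p.k_pmca, 1.0)
    per_ion = {"Ca": 2.0 * rate * e0}
    return PumpResult(per_ion["Ca"], per_ion, rate)


def i_nckx(vm: float, na: IonSpec, ca_os: float, k: IonSpec, p: ModelParameters) -> PumpResult:
    """K-dependent Na/Ca exchanger: 4 Na+ in, 1 Ca2+ + 1 K+ out per cycle.

    Simplified to saturation in outer-segment Ca2+ (the limiting substrate
    in the forward, Ca-extrusion mode) times a Na_i co-substrate Hill factor
    of order 4 (four Na+ carried per cycle); Vm does not modulate the
    simplified law.
    """
    if ca_os < 0:
        raise ValueError("Ca concentration must be non-negative")
    e0 = p.constants.e_pa
    rate = (
        p.i_max_nckx / e0
        * hill(ca_os, p.k_nckx, 1.0)
        * hill(na.conc_in, p.km_nckx_na, p.n_nckx_na)
    )
    if k.conc_in <= 0:
        rate = 0.0  # no counter-substrate
    per_ion = {
        "Na": -4.0 * rate * e0,
        "Ca": 2.0 * rate * e0,
        "K": rate * e0,
    }
    return PumpResult(sum(per_ion.values()), per_ion, rate)


def i_ncx(vm: float, na: IonSpec, ca_is: float, p: ModelParameters) -> PumpResult:
    """Na/Ca exchanger: 3 Na+ in, 1 Ca2+ out per cycle; minor pathway."""
    if ca_is < 0:
        raise ValueError("Ca concentration must be non-negative")
    e0 = p.constants.e_pa
    rate = p.r_max_ncx * hill(ca_is, p.k_ncx, 1.0)
    per_ion = {"Na": -3.0 * rate * e0, "Ca": 2.0 * rate * e0}
    return PumpResult(per_ion["Na"] + per_ion["Ca"], per_ion, rate)


def cotransporter_fluxes(
    vm: float,
    na: IonSpec,
    k: IonSpec,
    cl: IonSpec,
    p: ModelParameters,
) -> tuple[PumpResult, PumpResult]:
    """Electroneutral NKCC1 and KCC2 cycle rates and per-ion components.

    J_NKCC1 = U * ln([Na]o [K]o [Cl]o^2 / [Na]i [K]i [Cl]i^2), positive
    inward (Cl- uptake); J_KCC2 = U * ln([K]i [Cl]i / [K]o [Cl]o), positive
    outward (Cl- extrusion).  Both vanish at equilibrium of the transported
    product and carry zero net charge; Vm does not enter.
    """
    for ion in (na, k, cl):
        if ion.conc_in <= 0 or ion.conc_out <= 0:
            raise ValueError("concentrations must be strictly positive")
    e0 = p.constants.e_pa
    q1 = math.log(
        (na.conc_out * k.conc_out * cl.conc_out**2)
        / (na.conc_in * k.conc_in * cl.conc_in**2)
    )
    c1 = p.u_nkcc1 * q1  # cycles/s inward
    nkcc1 = PumpResult(
        0.0,
        {"Na": -c1 * e0, "K": -c1 * e0, "Cl": 2.0 * c1 * e0},
        c1,
    )
    q2 = math.log((k.conc_in * cl.conc_in) / (k.conc_out * cl.conc_out))
    c2 = p.u_kcc2 * q2  # cycles/s outward
    kcc2 = PumpResult(0.0, {"K": c2 * e0, "Cl": -c2 * e0}, c2)
    return nkcc1, kcc2


def leak_currents(
    vm: float,
    na: IonSpec,
    k: IonSpec,
    cl: IonSpec,
    ca_os: IonSpec,
    ca_is: IonSpec,
    leaks: LeakSet,
    constants: PhysicalConstants = CONSTANTS,
) -> dict:
    """The five fitted ohmic leaks, in pA (outward positive).

    Their conductances are the designated free parameters solved during
    calibration so that the dark steady state has zero net flux per species.
    """
    return {
        "L_K": leaks.g_l_k * (vm - nernst_potential(k, constants)),
        "L_Na": leaks.g_l_na * (vm - nernst_potential(na, constants)),
        "L_Cl": leaks.g_l_cl * (vm - nernst_potential(cl, constants)),
        "L_Caos": leaks.g_l_caos * (vm - nernst_potential(ca_os, constants)),
        "L_Cais": leaks.g_l_cais * (vm - nernst_potential(ca_is, constants)),
    }
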