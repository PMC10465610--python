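"""Two-compartment Ca2+ balance with buffering and inter-segment diffusion.

Free Ca2+ in the outer segment (os) is set by CNG influx, NCKX extrusion and
a fitted leak; free Ca2+ in the inner segment (is) by CaL influx, PMCA/NCX
extrusion and a fitted leak.  Each compartment has one low-affinity
mass-action buffer, and the two free pools exchange by linear diffusion
(positive direction os -> is):

    d[Ca]_os/dt = -(I_CNG,Ca - 2 I_NCKX + I_L,Caos) / (2 F V_os)
                  - d[Ca]_os,b/dt - J_dif / V_os
    d[Ca]_is/dt = -(I_CaL,Ca + I_PMCA - 2 I_NCX + I_L,Cais) / (2 F V_is)
                  - d[Ca]_is,b/dt + J_dif / V_is

Currents in pA (outward positive), volumes in litres, concentrations in muM,
J_dif in mol/s.  The -2*I factors convert the exchanger *net* currents (one
charge per cycle) into their two-charge Ca2+ component.
"""

from __future__ import annotations

from dataclasses import dataclass

from .driving import CONSTANTS, PhysicalConstants

__all__ = [
    "CalciumState",
    "CompartmentGeometry",
    "BufferSpec",
    "ca_os_derivative",
    "ca_is_derivative",
    "buffer_kinetics",
    "j_dif",
]


@dataclass(frozen=True)
class CalciumState:
    """Free and buffer-bound Ca2+ (muM) in each compartment."""

    ca_os_free: float
    ca_os_bound: float
    ca_is_free: float
    ca_is_bound: float

    def __post_init__(self) -> None:
        if min(self.ca_os_free, self.ca_os_bound, self.ca_is_free, self.ca_is_bound) < 0:
            raise ValueError("calcium state must be non-negative")


@dataclass(frozen=True)
class CompartmentGeometry:
    """Compartment volumes (L) and membrane capacitance (pF)."""

    v_os: float
    v_is: float
    c_m: float = 3.6

    def __post_init__(self) -> None:
        if self.v_os <= 0 or self.v_is <= 0 or self.c_m <= 0:
            raise ValueError("volumes and capacitance must be positive")

    @property
    def v_cell(self) -> float:
        return self.v_os + self.v_is


@dataclass(frozen=True)
class BufferSpec:
    """One mass-action buffer: total sites (muM), K_d (muM), on-rate (/muM/s)."""

    b_tot: float
    k_d: float
    k_on: float

    @property
    def k_off(self) -> float:
        return self.k_on * self.k_d

    def equilibrium_bound(self, free: float) -> float:
        return self.b_tot * free / (free + self.k_d)


def _pa_to_um_per_s(i_pa: float, volume: float, constants: PhysicalConstants) -> float:
    # pA of divalent current -> muM/s in `volume`
    return i_pa * 1e-6 / (2.0 * constants.F * volume)


def ca_os_derivative(
    i_cng_ca: float,
    i_nckx: float,
    i_l_caos: float,
    dbound_dt: float,
    j_dif_mol: float,
    geom: CompartmentGeometry,
    constants: PhysicalConstants = CONSTANTS,
) -> float:
    """d[Ca2+]_os/dt in muM/s.  ``i_nckx`` is the exchanger *net* current."""
    flux = -(i_cng_ca - 2.0 * i_nckx + i_l_caos)
    return (
        _pa_to_um_per_s(flux, geom.v_os, constants)
        - dbound_dt
        - j_dif_mol / geom.v_os * 1e6
    )


def ca_is_derivative(
    i_cal_ca: float,
    i_pmca: float,
    i_ncx: float,
    i_l_cais: float,
    dbound_dt: float,
    j_dif_mol: float,
    geom: CompartmentGeometry,
    constants: PhysicalConstants = CONSTANTS,
) -> float:
    """d[Ca2+]_is/dt in muM/s; diffusion enters with the opposite sign."""
    flux = -(i_cal_ca + i_pmca - 2.0 * i_ncx + i_l_cais)
    return (
        _pa_to_um_per_s(flux, geom.v_is, constants)
        - dbound_dt
        + j_dif_mol / geom.v_is * 1e6
    )


def buffer_kinetics(free: float, bound: float, buffer: BufferSpec) -> float:
    """d[bound]/dt (muM/s) from mass-action on/off kinetics."""
    if bound < 0 or bound > buffer.b_tot:
        raise ValueError("bound Ca outside buffer capacity")
    return buffer.k_on * free * (buffer.b_tot - bound) - buffer.k_off * bound


def j_dif(
    ca_os: float,
    ca_is: float,
    coupling_ions_per_um: float,
    constants: PhysicalConstants = CONSTANTS,
) -> float:
    """Inter-compartment diffusion flux in mol/s, positive os -> is.

    Proportional to the free-concentration difference; antisymmetric under
    swapping the compartments.
    """
    return coupling_ions_per_um * (ca_os - ca_is) / constants.N_A
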