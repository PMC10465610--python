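"""Electrodiffusive driving forces: Nernst reversal potentials and the
Goldman-Hodgkin-Katz (GHK) constant-field driving term.

Every channel current in the model is built from one of two driving-force
primitives:

* the Nernst (reversal) potential ``E_ion`` for ohmic single-ion channels,
* the GHK constant-field term ``C_F,ion`` for multi-ion channels, a
  concentration-weighted driving term (units mM) that vanishes exactly at the
  ion's Nernst potential and tends to ``[ion]_i - [ion]_o`` as ``Vm -> 0``.

Membrane potential is carried in mV everywhere, with explicit 1e-3 factors in
the exponent, so that no silent unit conversion hides inside these functions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "IonSpec",
    "PhysicalConstants",
    "CONSTANTS",
    "nernst_potential",
    "ghk_driving_term",
]

_VALENCES = {"Na": 1, "K": 1, "Ca": 2, "Cl": -1}


@dataclass(frozen=True)
class PhysicalConstants:
    """Fundamental constants (SI) plus the simulation temperature in K."""

    F: float = 96485.33212  # C mol^-1
    R: float = 8.31446261815324  # J mol^-1 K^-1
    T: float = 310.15  # K, mouse physiological; configurable
    N_A: float = 6.02214076e23  # mol^-1

    def __post_init__(self) -> None:
        if min(self.F, self.R, self.T, self.N_A) <= 0:
            raise ValueError("physical constants must be strictly positive")

    @property
    def e0(self) -> float:
        """Elementary charge in C (F / N_A)."""
        return self.F / self.N_A

    @property
    def e_pa(self) -> float:
        """Charge carried per ion per second, in pA (e0 * 1e12).

        Divide a charge component in pA by this to get ions/s.
        """
        return self.F / self.N_A * 1e12

    @property
    def rt_over_f(self) -> float:
        """Thermal voltage R*T/F in volts."""
        return self.R * self.T / self.F


CONSTANTS = PhysicalConstants()


@dataclass(frozen=True)
class IonSpec:
    """One permeant ion species with its transmembrane concentrations (mM)."""

    name: str
    z: int
    conc_out: float
    conc_in: float

    def __post_init__(self) -> None:
        if self.name not in _VALENCES:
            raise ValueError(f"unknown ion {self.name!r}")
        if self.z != _VALENCES[self.name]:
            raise ValueError(f"valence {self.z} inconsistent with {self.name}")
        if self.conc_out <= 0 or self.conc_in <= 0:
            raise ValueError("ion concentrations must be strictly positive")


def nernst_potential(ion: IonSpec, constants: PhysicalConstants = CONSTANTS) -> float:
    """Reversal potential in mV: (R*T)/(z*F*1e-3) * ln([ion]_o/[ion]_i).

    Antisymmetric under swapping the two concentrations.
    """
    if ion.conc_out <= 0 or ion.conc_in <= 0:
        raise ValueError("ion concentrations must be strictly positive")
    return (
        constants.R
        * constants.T
        / (ion.z * constants.F * 1e-3)
        * math.log(ion.conc_out / ion.conc_in)
    )


def ghk_driving_term(
    ion: IonSpec, vm: float, constants: PhysicalConstants = CONSTANTS
) -> float:
    """GHK constant-field driving term C_F,ion in mM at membrane potential ``vm``.

    C_F = u * ([i] - [o] e^{-u}) / (1 - e^{-u}),  u = z F Vm 1e-3 / (R T)

    The removable singularity at Vm = 0 is handled with a second-order Taylor
    branch for |u| < 1e-6:

    C_F ~= ([i] - [o]) + u ([i] + [o]) / 2 + u^2 ([i] - [o]) / 12
    """
    if not math.isfinite(vm):
        raise ValueError("membrane potential must be finite")
    ci, co = ion.conc_in, ion.conc_out
    if ci <= 0 or co <= 0:
        raise ValueError("ion concentrations must be strictly positive")
    u = ion.z * constants.F * vm * 1e-3 / (constants.R * constants.T)
    if abs(u) < 1e-6:
        return (ci - co) + u * (ci + co) / 2.0 + u * u * (ci - co) / 12.0
    emu = math.exp(-u)
    return u * (ci - co * emu) / (1.0 - emu)
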