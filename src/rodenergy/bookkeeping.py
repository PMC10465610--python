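"""Whole-cell ion bookkeeping: d[ion]/dt from the per-ion current breakdown.

Na+, K+ and Cl- are whole-cell pools (volume V_cell); only Ca2+ is
compartmentalized (see :mod:`rodenergy.calcium`).  Each pool's derivative
sums every pathway carrying that species, signed by direction and valence:

    d[ion]_i/dt = -I_ion / (z F V)

with outward current positive, which yields the charge/concentration
consistency identity  F * sum_ion z V_ion d[ion]_i/dt = -I_All  at every
instant (electroneutral cotransporter components cancel from I_All but not
from the pool derivatives).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

from .driving import CONSTANTS, PhysicalConstants

__all__ = ["IonPools", "CurrentBreakdown", "ion_derivatives", "charge_consistency"]

_Z = {"Na": 1, "K": 1, "Cl": -1, "Ca_os": 2, "Ca_is": 2}


@dataclass(frozen=True)
class IonPools:
    """Intracellular pools (mM for Na/K/Cl, muM for free Ca per compartment)."""

    na_i: float
    k_i: float
    cl_i: float
    ca_os: float
    ca_is: float

    def __post_init__(self) -> None:
        if min(self.na_i, self.k_i, self.cl_i, self.ca_os, self.ca_is) <= 0:
            raise ValueError("ion pools must be strictly positive")


@dataclass(frozen=True)
class CurrentBreakdown:
    """Every membrane pathway at an instant, decomposed per ion.

    ``components`` maps current name -> {ion label -> charge-equivalent pA,
    outward positive}; ion labels are Na, K, Cl, Ca_os, Ca_is.
    Electroneutral cotransporters appear with components that sum to zero.
    """

    components: Mapping[str, Mapping[str, float]] = field(default_factory=dict)

    def total(self, name: str) -> float:
        return sum(self.components[name].values())

    @property
    def i_all(self) -> float:
        return sum(sum(d.values()) for d in self.components.values())

    def ion_sum(self, ion: str) -> float:
        """Summed charge-equivalent current carried by one species (pA)."""
        return sum(d.get(ion, 0.0) for d in self.components.values())

    def component(self, name: str, ion: str) -> float:
        return self.components[name].get(ion, 0.0)


def ion_derivatives(
    breakdown: CurrentBreakdown,
    v_cell: float,
    v_os: float,
    v_is: float,
    constants: PhysicalConstants = CONSTANTS,
) -> dict:
    """Membrane-flux part of each pool derivative.

    Returns {Na, K, Cl} in mM/s and {Ca_os, Ca_is} in muM/s (buffer and
    diffusion terms are handled by :mod:`rodenergy.calcium`).  Raises if a
    current carries an unknown species label (no per-ion decomposition).
    """
    for name, comp in breakdown.components.items():
        for ion in comp:
            if ion not in _Z:
                raise ValueError(f"current {name} has undecomposed component {ion!r}")
    f = constants.F
    return {
        "Na": -breakdown.ion_sum("Na") * 1e-9 / (f * v_cell),
        "K": -breakdown.ion_sum("K") * 1e-9 / (f * v_cell),
        "Cl": breakdown.ion_sum("Cl") * 1e-9 / (f * v_cell),
        "Ca_os": -breakdown.ion_sum("Ca_os") * 1e-6 / (2.0 * f * v_os),
        "Ca_is": -breakdown.ion_sum("Ca_is") * 1e-6 / (2.0 * f * v_is),
    }


def charge_consistency(
    breakdown: CurrentBreakdown,
    derivs: Mapping[str, float],
    v_cell: float,
    v_os: float,
    v_is: float,
    constants: PhysicalConstants = CONSTANTS,
) -> tuple[float, float]:
    """Both sides of the charge/concentration identity, in pA.

    Returns (F * sum_ion z V d[ion]/dt, -I_All); they agree to rounding at
    every valid evaluation.
    """
    f = constants.F
    lhs = (
        f * v_cell * (derivs["Na"] + derivs["K"] - derivs["Cl"]) * 1e9
        + 2.0 * f * v_os * derivs["Ca_os"] * 1e6
        + 2.0 * f * v_is * derivs["Ca_is"] * 1e6
    )
    return lhs, -breakdown.i_all
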