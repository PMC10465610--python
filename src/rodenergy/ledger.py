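"""ATP accounting and attribution of extrusion cost to source currents.

The rod pays for ion homeostasis through two ATPases:

* the Na/K pump removes Na+ at 3 ions per ATP, so the ATP rate needed to
  clear a Na+ influx is  d[Na]_influx/dt * N_A * V_cell / 3 * 1e-3
  (influx in mM/s), attributable per source current;
* the PMCA removes inner-segment Ca2+ at 1 ion per ATP:
  d[Ca]_influx/dt * N_A * V_is * 1e-6  (influx in muM/s).

Attribution is by instantaneous influx decomposition (the ledger's
"influx-attributed" rates); in transients the pumps lag the influx, so the
pumps' actual hydrolysis rates are reported alongside.  The cascade term is
computed in :mod:`rodenergy.cascade`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

from .bookkeeping import CurrentBreakdown
from .driving import CONSTANTS, PhysicalConstants

__all__ = [
    "NA_SOURCES",
    "K_EFFLUX_SOURCES",
    "EnergyLedger",
    "atp_rate_for_na",
    "atp_rate_for_ca",
    "decompose_na_influx",
    "decompose_k_efflux",
    "compute_ledger",
    "total_atp",
]

# Na-uptake pathways whose load the Na/K pump must clear
NA_SOURCES = ("I_CNG", "I_NCKX", "I_h", "I_CaL", "I_NCX", "J_NKCC1", "I_L_Na")
# K-extrusion pathways (outward K components)
K_EFFLUX_SOURCES = (
    "I_Kv", "I_CNG", "I_h", "I_NCKX", "I_KCa", "I_CaL", "J_KCC2", "I_L_K",
)


@dataclass(frozen=True)
class EnergyLedger:
    """Instantaneous ATP rates (molecules/s)."""

    atp_nak_total: float
    atp_nak_by_source: Mapping[str, float] = field(default_factory=dict)
    atp_pmca: float = 0.0
    atp_cascade: float = 0.0
    # pump-actual hydrolysis rates (may lag the influx-attributed rates)
    atp_nak_pump: float = 0.0
    atp_pmca_pump: float = 0.0

    @property
    def total(self) -> float:
        return self.atp_nak_total + self.atp_pmca + self.atp_cascade


def atp_rate_for_na(
    na_influx_mm_per_s: float,
    v_cell: float,
    constants: PhysicalConstants = CONSTANTS,
) -> float:
    """ATP rate to extrude a Na+ influx given in mM/s over V_cell (litres)."""
    if na_influx_mm_per_s < 0:
        raise ValueError("influx rate must be non-negative")
    return na_influx_mm_per_s * constants.N_A * v_cell / 3.0 * 1e-3


def atp_rate_for_ca(
    ca_influx_um_per_s: float,
    v_is: float,
    constants: PhysicalConstants = CONSTANTS,
) -> float:
    """ATP rate to extrude an inner-segment Ca2+ influx given in muM/s."""
    if ca_influx_um_per_s < 0:
        raise ValueError("influx rate must be non-negative")
    return ca_influx_um_per_s * constants.N_A * v_is * 1e-6


def _na_influx_ions(breakdown: CurrentBreakdown, e0: float) -> dict:
    out = {}
    for name in NA_SOURCES:
        if name not in breakdown.components:
            continue
        comp = breakdown.component(name, "Na")
        out[name] = max(0.0, -comp) / e0
    return out


def decompose_na_influx(
    breakdown: CurrentBreakdown, constants: PhysicalConstants = CONSTANTS
) -> dict:
    """Fractional share of total Na+ influx per source current.

    Returns an empty mapping when the total influx is zero.
    """
    ions = _na_influx_ions(breakdown, constants.e_pa)
    total = sum(ions.values())
    if total <= 0.0:
        return {}
    return {name: flux / total for name, flux in ions.items()}


def decompose_k_efflux(
    breakdown: CurrentBreakdown, constants: PhysicalConstants = CONSTANTS
) -> dict:
    """Fractional share of total K+ extrusion per outward-K pathway."""
    e0 = constants.e_pa
    effl = {}
    for name in K_EFFLUX_SOURCES:
        if name not in breakdown.components:
            continue
        comp = breakdown.component(name, "K")
        effl[name] = max(0.0, comp) / e0
    total = sum(effl.values())
    if total <= 0.0:
        return {}
    return {name: flux / total for name, flux in effl.items()}


def compute_ledger(
    breakdown: CurrentBreakdown,
    cascade_atp: float,
    v_is: float,
    j_dif_ions: float = 0.0,
    nak_pump_rate: float = 0.0,
    pmca_pump_rate: float = 0.0,
    constants: PhysicalConstants = CONSTANTS,
) -> EnergyLedger:
    """Assemble the ledger from a current breakdown.

    ``j_dif_ions`` is the OS->IS diffusion flux in ions/s (a Ca2+ source for
    the inner segment, hence part of the PMCA-attributed influx).
    """
    e0 = constants.e_pa
    na_ions = _na_influx_ions(breakdown, e0)
    by_source = {name: flux / 3.0 for name, flux in na_ions.items()}
    # inner-segment Ca influx: CaL + Ca leak (+ reverse-mode exchangers) + diffusion
    ca_influx = max(0.0, j_dif_ions)
    for name in ("I_CaL", "I_L_Cais", "I_NCX", "I_PMCA"):
        if name in breakdown.components:
            ca_influx += max(0.0, -breakdown.component(name, "Ca_is")) / (2.0 * e0)
    return EnergyLedger(
        atp_nak_total=sum(by_source.values()),
        atp_nak_by_source=by_source,
        atp_pmca=ca_influx,
        atp_cascade=cascade_atp,
        atp_nak_pump=nak_pump_rate,
        atp_pmca_pump=pmca_pump_rate,
    )


def total_atp(ledger: EnergyLedger) -> float:
    """Total instantaneous ATP rate: NaK + PMCA + cascade."""
    return ledger.total
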