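"""Gated membrane channel currents.

Two current families:

* single-ion ohmic channels ``I = g * m^M * h * (Vm - E_ion)`` for the
  delayed-rectifier K+ current (Kv), the Ca-activated K+ current (KCa) and the
  Ca-activated Cl- current (ClCa);
* multi-ion GHK channels ``I = g * m^M * h * sum_ion w_ion * C_F,ion`` for the
  cyclic-nucleotide-gated channel (CNG), the hyperpolarization-activated
  current (h-current, HCN1) and the L-type Ca channel (CaL), where ``w_ion``
  are relative permeability weights and ``C_F`` is the GHK constant-field
  driving term.

Sign convention throughout the package: outward current positive, inward
negative (in pA).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

from .driving import CONSTANTS, IonSpec, PhysicalConstants, ghk_driving_term

__all__ = [
    "GateSpec",
    "ChannelSpec",
    "ChannelCurrent",
    "boltzmann",
    "hill",
    "gating_step",
    "single_ion_current",
    "multi_ion_current",
    "cng_open_fraction",
]


def boltzmann(vm: float, v_half: float, slope: float) -> float:
    """Sigmoid activation 1 / (1 + exp((v_half - vm)/slope)).

    Positive ``slope`` gives activation with depolarization; negative slope
    gives activation with hyperpolarization (h-type gates).
    """
    return 1.0 / (1.0 + math.exp((v_half - vm) / slope))


def hill(x: float, k: float, n: float) -> float:
    """Hill saturation x^n / (x^n + k^n), defined as 0 at x = 0."""
    if x <= 0.0:
        return 0.0
    xn = x**n
    return xn / (xn + k**n)


@dataclass(frozen=True)
class GateSpec:
    """First-order gate: steady-state curve, voltage-dependent time constant
    (seconds) and integer gating exponent M."""

    steady_state: Callable[[float], float]
    time_constant: Callable[[float], float]
    exponent: int = 1

    def __post_init__(self) -> None:
        if self.exponent < 1:
            raise ValueError("gating exponent must be a positive integer")


@dataclass(frozen=True)
class ChannelSpec:
    """Channel conductance/permeability block.

    ``g`` is the maximal conductance (pA/mV for ohmic channels, pA/mM for GHK
    channels).  ``ions`` lists the permitted species; ``weights`` holds the
    relative permeability weight of each permitted ion (ohmic channels have a
    single implicit weight of 1).
    """

    name: str
    g: float
    ions: Sequence[str]
    weights: Mapping[str, float] = field(default_factory=dict)
    exponent: int = 1

    def __post_init__(self) -> None:
        if not self.ions:
            raise ValueError("channel must permit at least one ion")
        if self.g < 0:
            raise ValueError("conductance must be non-negative")
        for w in self.weights.values():
            if w < 0:
                raise ValueError("permeability weights must be non-negative")


@dataclass(frozen=True)
class ChannelCurrent:
    """A channel current with its per-ion decomposition (pA, outward +)."""

    total: float
    per_ion: Mapping[str, float]


def gating_step(gate_value: float, gate: GateSpec, vm: float, dt: float) -> float:
    """One forward-Euler step of first-order gate relaxation.

    dm/dt = (m_inf(Vm) - m) / tau(Vm); the result is clamped to [0, 1].
    ``dt`` in seconds.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    m_inf = gate.steady_state(vm)
    tau = gate.time_constant(vm)
    if tau <= 0:
        raise ValueError("gate time constant must be positive")
    m = gate_value + dt * (m_inf - gate_value) / tau
    return min(1.0, max(0.0, m))


def single_ion_current(
    spec: ChannelSpec, m: float, h: float, vm: float, e_ion: float
) -> ChannelCurrent:
    """Ohmic gated current I = g * m^M * h * (Vm - E_ion) for one of K+/Cl-."""
    if len(spec.ions) != 1 or spec.ions[0] not in ("K", "Cl"):
        raise ValueError("single-ion channels carry exactly one of K+ or Cl-")
    i = spec.g * m**spec.exponent * h * (vm - e_ion)
    return ChannelCurrent(total=i, per_ion={spec.ions[0]: i})


def multi_ion_current(
    spec: ChannelSpec,
    m: float,
    h: float,
    vm: float,
    ions: Sequence[IonSpec],
    constants: PhysicalConstants = CONSTANTS,
) -> ChannelCurrent:
    """GHK gated current I = g * m^M * h * sum_ion w_ion * C_F,ion.

    Each per-ion component vanishes at that ion's Nernst potential.
    """
    if not set(spec.ions) <= {"Ca", "K", "Na"}:
        raise ValueError("multi-ion channels carry a subset of {Ca, K, Na}")
    gate = spec.g * m**spec.exponent * h
    per_ion = {}
    for ion in ions:
        if ion.name not in spec.ions:
            continue
        w = spec.weights.get(ion.name, 1.0)
        per_ion[ion.name] = gate * w * ghk_driving_term(ion, vm, constants)
    return ChannelCurrent(total=sum(per_ion.values()), per_ion=per_ion)


def cng_open_fraction(
    cgmp: float,
    ca_os: float,
    k_half: float = 20.0,
    n: float = 3.0,
    k_ca_mod: float = 10.0,
) -> float:
    """Open fraction of the CNG channel given its two messengers.

    Hill activation by cGMP (muM) with cooperativity ``n``; Ca2+/calmodulin
    feedback desensitizes the channel by scaling the half-activation constant:
    K_1/2(Ca) = k_half * (1 + Ca_os / k_ca_mod).  Monotone increasing in cGMP,
    monotone decreasing in Ca_os, bounded in [0, 1].
    """
    if cgmp < 0 or ca_os < 0:
        raise ValueError("messenger concentrations must be non-negative")
    if cgmp == 0.0:
        return 0.0
    k_eff = k_half * (1.0 + ca_os / k_ca_mod)
    return hill(cgmp, k_eff, n)
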