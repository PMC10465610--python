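"""Phototransduction cascade: photons -> R* -> activated effector -> cGMP.

Deterministic lumped scheme of the standard rod cascade lineage:

    dR*/dt  = phi(t) - R*/tau_R
    dE*/dt  = nu_RE * R* - E*/tau_E
    d[cG]/dt = alpha(Ca_os) - (beta_dark + k_E * E*) * [cG]

where ``phi`` is the photoisomerization rate (stimulus intensity in photons
mum^-2 s^-1 times the collecting area), ``E*`` counts activated
phosphodiesterase effector units, and the guanylate-cyclase synthesis rate
``alpha`` rises as outer-segment Ca2+ falls (negative-feedback loop):

    alpha(Ca) = alpha_max / (1 + (Ca / K_cyc)^n_cyc)

Cascade ATP accounting uses three config-exposed cost weights: high-energy
phosphates per R* shutoff (phosphorylation), per effector activation (GTP
turnover) and per cGMP synthesized (GTP -> cGMP).
"""

from __future__ import annotations

from dataclasses import dataclass

from .params import ModelParameters

__all__ = [
    "CascadeState",
    "StimulusProtocol",
    "photoisomerization_rate",
    "cascade_derivatives",
    "cyclase_rate",
    "cascade_atp_rate",
]


@dataclass(frozen=True)
class CascadeState:
    """Activated rhodopsin and effector counts (molecules) plus cGMP (muM)."""

    r_star: float
    e_star: float
    cgmp: float

    def __post_init__(self) -> None:
        if self.r_star < 0 or self.e_star < 0 or self.cgmp < 0:
            raise ValueError("cascade state components must be non-negative")


@dataclass(frozen=True)
class StimulusProtocol:
    """Light stimulus: dark, a rectangular flash, or a constant step.

    ``intensity`` in photons mum^-2 s^-1; ``onset`` and ``duration`` in s.
    A "flash" is a 20-ms rectangular step by default.
    """

    kind: str = "dark"
    intensity: float = 0.0
    onset: float = 0.0
    duration: float = 0.02

    def __post_init__(self) -> None:
        if self.kind not in ("dark", "flash", "step"):
            raise ValueError(f"unknown stimulus kind {self.kind!r}")
        if self.intensity < 0:
            raise ValueError("intensity must be non-negative")
        if self.kind != "dark" and self.duration <= 0:
            raise ValueError("flash/step duration must be positive")

    def intensity_at(self, t: float) -> float:
        if self.kind == "dark" or self.intensity == 0.0:
            return 0.0
        if self.onset <= t < self.onset + self.duration:
            return self.intensity
        return 0.0


def photoisomerization_rate(j_hv: float, collecting_area: float = 0.43) -> float:
    """R* per second: photon flux density times the rod's collecting area."""
    if j_hv < 0 or collecting_area < 0:
        raise ValueError("intensity and collecting area must be non-negative")
    return j_hv * collecting_area


def cyclase_rate(ca_os: float, p: ModelParameters) -> float:
    """Guanylate-cyclase cGMP synthesis rate (muM/s), Ca-inhibited."""
    return p.alpha_max / (1.0 + (ca_os / p.k_cyc) ** p.n_cyc)


def cascade_derivatives(
    state: CascadeState, ca_os: float, r_star_rate: float, p: ModelParameters
) -> tuple[float, float, float]:
    """Time derivatives (dR*/dt, dE*/dt, d[cG]/dt)."""
    dr = r_star_rate - state.r_star / p.tau_r
    de = p.nu_re * state.r_star - state.e_star / p.tau_e
    beta = p.beta_dark + p.k_e * state.e_star
    dcg = cyclase_rate(ca_os, p) - beta * state.cgmp
    return dr, de, dcg


def cascade_atp_rate(state: CascadeState, ca_os: float, p: ModelParameters) -> float:
    """Cascade ATP consumption in molecules of high-energy phosphate per s.

    Sum of R* phosphorylation (rate R*/tau_R), effector GTP turnover
    (nu_RE * R*, weighted) and cGMP synthesis (cyclase rate over the
    outer-segment volume).  In darkness only the basal cGMP turnover remains;
    the stimulus-driven terms are proportional to R* and hence grow linearly
    with light intensity.
    """
    c = p.constants
    synth_molecules = cyclase_rate(ca_os, p) * 1e-6 * p.v_os * c.N_A
    return (
        p.w_atp_phos * state.r_star / p.tau_r
        + p.w_atp_gtp * p.nu_re * state.r_star
        + p.w_atp_cg * synth_molecules
    )
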