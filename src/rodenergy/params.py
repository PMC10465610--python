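"""Model parameters and the dark-state calibration solve.

The model is a two-compartment (outer segment / inner segment + cell body +
synaptic terminal) mouse rod photoreceptor with 13 membrane pathways, a
phototransduction cascade and an ATP ledger.  Its free magnitudes
(conductances, pump maxima, cotransporter scales, the five leak conductances)
are not tuned by hand: :func:`calibrate_parameters` solves them in closed form
so that a designed dark operating point is an exact steady state with

* zero net flux for every ion species (the stated role of the leak currents),
* the published dark flux decomposition: Na+ uptake 65% CNG / 14% NCKX /
  20% h-current / 1% others of a 1.5e8 ions/s turnover (5e7 ATP/s through the
  Na/K pump at 3 Na+ per ATP), K+ extrusion 49.5% Kv / 20.9% CNG / 19.3%
  h-current, a -15 pA outer-segment dark current split 94.4:5.6 between CNG
  and NCKX, Na+ carrying 90% of the CNG influx charge, and 2e7 Ca2+ ions/s
  (= ATP/s) extruded by the PMCA pump.

Gating-curve shape parameters (Boltzmann midpoints/slopes, time constants)
and cascade kinetics were calibrated once against the flash and constant-light
electrophysiology anchors and are frozen here as defaults.

Units: mV, pA, nS-equivalent conductances (pA/mV ohmic, pA/mM GHK), mM for
Na/K/Cl, muM for Ca and cGMP, litres for volumes, pF for capacitance,
seconds for time, ions/s or molecules/s for fluxes.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Any

import yaml

from .channels import boltzmann, cng_open_fraction, hill
from .driving import CONSTANTS, IonSpec, PhysicalConstants, ghk_driving_term, nernst_potential

__all__ = [
    "DarkTargets",
    "ModelParameters",
    "calibrate_parameters",
    "default_parameters",
    "load_parameters",
    "save_parameters",
]


@dataclass(frozen=True)
class DarkTargets:
    """The designed dark operating point and the published flux decomposition
    that the calibration solve reproduces exactly."""

    # dark operating point
    vm_dark: float = -36.2  # mV
    na_i: float = 10.0  # mM
    k_i: float = 140.0  # mM
    cl_i: float = 30.0  # mM
    ca_os: float = 0.3  # muM free, outer segment
    ca_is: float = 0.1  # muM free, inner segment
    cg_dark: float = 4.0  # muM cGMP

    # Na+/K+ pump turnover and the Na-uptake decomposition
    atp_nak: float = 5.0e7  # ATP/s in darkness => 1.5e8 Na+ ions/s extruded
    share_na_cng: float = 0.65
    share_na_nckx: float = 0.14
    share_na_h: float = 0.20
    # K-extrusion shares (fractions of total K+ turnover)
    share_k_kv: float = 0.495
    share_k_cng: float = 0.209
    # CNG influx charge carried by Na+ (the rest is Ca2+)
    cng_na_charge_fraction: float = 0.90
    # Ca handling (ions/s)
    pmca_efflux: float = 2.0e7
    ncx_cycles: float = 1.0e5
    cal_ca_influx: float = 1.8e7
    cal_na_influx: float = 3.0e5
    cal_k_efflux: float = 1.0e5
    j_dif_ions: float = 2.0e5  # OS -> IS diffusion in darkness
    # minor K/Cl pathways (ions/s)
    kca_efflux: float = 4.1e6
    kcc2_efflux: float = 3.0e5
    l_cl_efflux: float = 1.0e5
    # Na/K pump voltage factor at the dark potential
    nak_fv_dark: float = 0.8


@dataclass(frozen=True)
class ModelParameters:
    """Complete parameter set; construct via :func:`calibrate_parameters`."""

    constants: PhysicalConstants = CONSTANTS
    dark: DarkTargets = field(default_factory=DarkTargets)

    # fixed extracellular milieu (mM)
    na_o: float = 145.0
    k_o: float = 5.0
    cl_o: float = 110.0
    ca_o: float = 2.0

    # geometry
    v_os: float = 2.0e-14  # L, outer-segment cytosol
    v_is: float = 8.0e-14  # L, inner segment + cell body + terminal
    c_m: float = 3.6  # pF
    collecting_area: float = 0.43  # mum^2

    # CNG channel (I_CNG)
    g_cng: float = 0.0  # pA/mM, solved
    w_cng_na: float = 1.0
    w_cng_ca: float = 0.0  # solved
    w_cng_k: float = 0.0  # solved
    k_cng: float = 20.0  # muM cGMP half-activation (dark Ca)
    n_cng: float = 3.0
    k_cng_camod: float = 10.0  # muM, Ca/CaM desensitization scale

    # h-current (I_h, HCN1)
    g_h: float = 0.0  # solved
    w_h_na: float = 0.33  # P_Na/P_K
    vhalf_h: float = -75.4
    slope_h: float = -10.1  # negative: activates on hyperpolarization
    tau_h_max: float = 0.127  # s
    vtau_h: float = -75.0
    ktau_h: float = 20.0

    # L-type Ca channel (I_CaL)
    g_cal: float = 0.0  # solved
    w_cal_na: float = 0.0  # solved
    w_cal_k: float = 0.0  # solved
    vhalf_cal: float = -30.0
    slope_cal: float = 6.4
    tau_cal: float = 0.005

    # delayed-rectifier K (I_Kv)
    g_kv: float = 0.0  # solved
    vhalf_kv: float = -25.0
    slope_kv: float = 18.0
    tau_kv: float = 0.008

    # Ca-activated K (I_KCa)
    g_kca: float = 0.0  # solved
    k_kca: float = 0.3  # muM
    n_kca: float = 2.0
    kca_enabled: bool = True

    # Ca-activated Cl (I_ClCa)
    g_clca: float = 1.45  # pA/mV; fitted to the flash transient
    k_clca: float = 0.5  # muM
    n_clca: float = 2.0
    tau_clca: float = 0.068  # s, activation kinetics

    # Na/K pump (I_NaK): Boltzmann voltage factor x substrate saturation
    i_max_nak: float = 0.0  # pA net, solved
    vhalf_nak: float = 0.0  # solved from nak_fv_dark
    slope_nak: float = 27.4
    km_nak_na: float = 1.3  # mM
    n_nak_na: float = 3.0
    km_nak_k: float = 1.0  # mM
    n_nak_k: float = 2.0

    # PMCA pump
    p_max_pmca: float = 0.0  # ions/s, solved
    k_pmca: float = 0.1  # muM

    # NCKX exchanger (4 Na in : 1 Ca + 1 K out)
    i_max_nckx: float = 0.0  # pA net magnitude, solved
    k_nckx: float = 1.5  # muM
    km_nckx_na: float = 0.0  # mM, optional Na_i co-substrate factor (0 = off)
    n_nckx_na: float = 4.0

    # NCX exchanger (3 Na in : 1 Ca out)
    r_max_ncx: float = 0.0  # cycles/s, solved
    k_ncx: float = 1.0  # muM

    # electroneutral cotransporters (thermodynamic log-ratio laws)
    u_nkcc1: float = 0.0  # cycles/s per ln-unit, solved
    u_kcc2: float = 0.0  # solved

    # leak conductances (solved by dark-state closure)
    g_l_k: float = 0.0
    g_l_na: float = 0.0
    g_l_cl: float = 0.0
    g_l_caos: float = 0.0
    g_l_cais: float = 0.0

    # Ca buffers (mass action, one low-affinity buffer per compartment)
    btot_os: float = 50.0  # muM
    kd_os: float = 2.0  # muM
    kon_os: float = 50.0  # /muM/s
    btot_is: float = 1000.0
    kd_is: float = 2.0
    kon_is: float = 20.0
    # OS <-> IS free-Ca diffusion coupling, ions/s per muM difference
    g_dif: float = 2.0e6

    # phototransduction cascade
    tau_r: float = 0.054  # s, R* lifetime
    tau_e: float = 0.11  # s, activated-PDE lifetime
    nu_re: float = 1300.0  # effector activations per R* per s
    k_e: float = 0.29  # /s hydrolysis rate per activated effector
    beta_dark: float = 4.6  # /s dark cGMP turnover
    cyc_span: float = 1.2  # alpha_max / alpha_dark
    n_cyc: float = 2.0
    alpha_max: float = 0.0  # muM/s, solved
    k_cyc: float = 0.0  # muM, solved

    # cascade ATP cost weights (effective, see methods note)
    w_atp_phos: float = 1.0  # per R* shutoff
    w_atp_gtp: float = 1.5  # per effector activation
    w_atp_cg: float = 1.0  # per cGMP synthesized

    # deterministic model: seed accepted for interface parity, never used
    seed: int = 0

    # ------------------------------------------------------------------
    def ion(self, name: str, compartment: str = "is") -> IonSpec:
        """IonSpec for the dark design concentrations (Ca per compartment)."""
        d = self.dark
        if name == "Na":
            return IonSpec("Na", 1, self.na_o, d.na_i)
        if name == "K":
            return IonSpec("K", 1, self.k_o, d.k_i)
        if name == "Cl":
            return IonSpec("Cl", -1, self.cl_o, d.cl_i)
        if name == "Ca":
            ca = d.ca_os if compartment == "os" else d.ca_is
            return IonSpec("Ca", 2, self.ca_o, ca * 1e-3)
        raise KeyError(name)

    @property
    def v_cell(self) -> float:
        return self.v_os + self.v_is


def _replace(p: ModelParameters, **kw: Any) -> ModelParameters:
    return dataclasses.replace(p, **kw)


def calibrate_parameters(
    dark: DarkTargets | None = None, base: ModelParameters | None = None
) -> ModelParameters:
    """Solve all free magnitudes so the dark design point is an exact fixed point.

    The solve is purely algebraic: every channel/pump law is evaluated at the
    dark operating point and its scale factor is chosen so the pathway carries
    exactly its target dark flux; the five leak conductances then close each
    species' flux balance to zero.  Because every species balances, the total
    membrane current at the dark potential is zero automatically.
    """
    dark = dark if dark is not None else (base.dark if base else DarkTargets())
    p = _replace(base or ModelParameters(), dark=dark)
    c = p.constants
    e0 = c.e_pa  # pA per ion/s
    vm = dark.vm_dark

    na = IonSpec("Na", 1, p.na_o, dark.na_i)
    k = IonSpec("K", 1, p.k_o, dark.k_i)
    cl = IonSpec("Cl", -1, p.cl_o, dark.cl_i)
    ca_os = IonSpec("Ca", 2, p.ca_o, dark.ca_os * 1e-3)
    ca_is = IonSpec("Ca", 2, p.ca_o, dark.ca_is * 1e-3)

    cf_na = ghk_driving_term(na, vm, c)
    cf_k = ghk_driving_term(k, vm, c)
    cf_ca_os = ghk_driving_term(ca_os, vm, c)
    cf_ca_is = ghk_driving_term(ca_is, vm, c)
    e_k = nernst_potential(k, c)
    e_na = nernst_potential(na, c)
    e_cl = nernst_potential(cl, c)
    e_ca_os = nernst_potential(ca_os, c)
    e_ca_is = nernst_potential(ca_is, c)

    # --- Na side: total turnover fixed by the NaK ATP anchor -------------
    na_total = 3.0 * dark.atp_nak  # ions/s extruded = total influx
    cng_na = dark.share_na_cng * na_total
    nckx_rate = dark.share_na_nckx * na_total / 4.0  # cycles/s
    ih_na = dark.share_na_h * na_total

    # --- Cl side first (ClCa conductance is frozen, flux is emergent) ----
    m_clca = hill(dark.ca_is, p.k_clca, p.n_clca)
    i_clca = p.g_clca * m_clca * (vm - e_cl)  # pA; < 0 means Cl efflux
    clca_efflux = -i_clca / e0
    if clca_efflux < 0:
        raise ValueError("dark design expects ClCa to run as a Cl- efflux")
    nkcc1_cycles = (clca_efflux + dark.kcc2_efflux + dark.l_cl_efflux) / 2.0

    # --- K side: total turnover = pump uptake + NKCC1 uptake -------------
    k_total = 2.0 * dark.atp_nak + nkcc1_cycles
    kv_k = dark.share_k_kv * k_total
    cng_k = dark.share_k_cng * k_total

    # --- CNG: conductance and permeability weights -----------------------
    f_dark = cng_open_fraction(dark.cg_dark, dark.ca_os, p.k_cng, p.n_cng, p.k_cng_camod)
    g_cng = cng_na * e0 / (f_dark * (-cf_na))
    # Ca carries (1 - fraction) of the CNG influx charge
    cng_ca_ions = cng_na * (1.0 - dark.cng_na_charge_fraction) / (
        dark.cng_na_charge_fraction * 2.0
    )
    w_cng_ca = 2.0 * e0 * cng_ca_ions / (g_cng * f_dark * (-cf_ca_os))
    w_cng_k = cng_k * e0 / (g_cng * f_dark * cf_k)

    # --- h-current -------------------------------------------------------
    m_h = boltzmann(vm, p.vhalf_h, p.slope_h)
    g_h = ih_na * e0 / (m_h * p.w_h_na * (-cf_na))
    ih_k = g_h * m_h * cf_k / e0  # emergent K efflux, ions/s

    # --- CaL -------------------------------------------------------------
    m_cal = boltzmann(vm, p.vhalf_cal, p.slope_cal)
    g_cal = 2.0 * e0 * dark.cal_ca_influx / (m_cal * (-cf_ca_is))
    w_cal_na = dark.cal_na_influx * e0 / (g_cal * m_cal * (-cf_na))
    w_cal_k = dark.cal_k_efflux * e0 / (g_cal * m_cal * cf_k)

    # --- Kv / KCa --------------------------------------------------------
    m_kv = boltzmann(vm, p.vhalf_kv, p.slope_kv)
    g_kv = kv_k * e0 / (m_kv * (vm - e_k))
    m_kca = hill(dark.ca_is, p.k_kca, p.n_kca)
    g_kca = dark.kca_efflux * e0 / (m_kca * (vm - e_k)) if p.kca_enabled else 0.0
    kca_efflux = dark.kca_efflux if p.kca_enabled else 0.0

    # --- pumps and exchangers -------------------------------------------
    vhalf_nak = vm + p.slope_nak * math.log(1.0 / dark.nak_fv_dark - 1.0)
    h_na = hill(dark.na_i, p.km_nak_na, p.n_nak_na)
    h_k = hill(p.k_o, p.km_nak_k, p.n_nak_k)
    i_max_nak = dark.atp_nak * e0 / (dark.nak_fv_dark * h_na * h_k)
    p_max_pmca = dark.pmca_efflux / hill(dark.ca_is, p.k_pmca, 1.0)
    i_max_nckx = nckx_rate * e0 / (
        hill(dark.ca_os, p.k_nckx, 1.0) * hill(dark.na_i, p.km_nckx_na, p.n_nckx_na)
    )
    r_max_ncx = dark.ncx_cycles / hill(dark.ca_is, p.k_ncx, 1.0)

    # --- cotransporters --------------------------------------------------
    q_nkcc1 = math.log(
        (p.na_o * p.k_o * p.cl_o**2) / (dark.na_i * dark.k_i * dark.cl_i**2)
    )
    q_kcc2 = math.log((dark.k_i * dark.cl_i) / (p.k_o * p.cl_o))
    u_nkcc1 = nkcc1_cycles / q_nkcc1
    u_kcc2 = dark.kcc2_efflux / q_kcc2

    # --- leak closures ---------------------------------------------------
    l_na = na_total - (
        cng_na + 4.0 * nckx_rate + ih_na + nkcc1_cycles
        + 3.0 * dark.ncx_cycles + dark.cal_na_influx
    )
    l_k = k_total - (
        kv_k + cng_k + ih_k + nckx_rate + kca_efflux
        + dark.cal_k_efflux + dark.kcc2_efflux
    )
    cng_ca = cng_na * (1.0 - dark.cng_na_charge_fraction) / (
        dark.cng_na_charge_fraction * 2.0
    )
    l_caos = nckx_rate + dark.j_dif_ions - cng_ca
    l_cais = dark.pmca_efflux + dark.ncx_cycles - (
        dark.cal_ca_influx + dark.j_dif_ions
    )
    for name, val in (
        ("Na", l_na), ("K", l_k), ("Ca_os", l_caos), ("Ca_is", l_cais)
    ):
        if val < 0:
            raise ValueError(f"dark design gives negative {name} leak ({val:.3g})")
    g_l_na = l_na * e0 / (e_na - vm)
    g_l_k = l_k * e0 / (vm - e_k)
    g_l_cl = dark.l_cl_efflux * e0 / (e_cl - vm)
    g_l_caos = 2.0 * e0 * l_caos / (e_ca_os - vm)
    g_l_cais = 2.0 * e0 * l_cais / (e_ca_is - vm)

    # --- cascade fixed point --------------------------------------------
    alpha_dark = p.beta_dark * dark.cg_dark
    alpha_max = p.cyc_span * alpha_dark
    k_cyc = dark.ca_os / (p.cyc_span - 1.0) ** (1.0 / p.n_cyc)

    g_dif = dark.j_dif_ions / (dark.ca_os - dark.ca_is)

    return _replace(
        p,
        g_cng=g_cng, w_cng_ca=w_cng_ca, w_cng_k=w_cng_k,
        g_h=g_h, g_cal=g_cal, w_cal_na=w_cal_na, w_cal_k=w_cal_k,
        g_kv=g_kv, g_kca=g_kca,
        i_max_nak=i_max_nak, vhalf_nak=vhalf_nak,
        p_max_pmca=p_max_pmca, i_max_nckx=i_max_nckx, r_max_ncx=r_max_ncx,
        u_nkcc1=u_nkcc1, u_kcc2=u_kcc2,
        g_l_k=g_l_k, g_l_na=g_l_na, g_l_cl=g_l_cl,
        g_l_caos=g_l_caos, g_l_cais=g_l_cais,
        alpha_max=alpha_max, k_cyc=k_cyc, g_dif=g_dif,
    )


def default_parameters() -> ModelParameters:
    """The calibrated default model."""
    return calibrate_parameters(DarkTargets())


# ----------------------------------------------------------------------
# YAML round trip
# ----------------------------------------------------------------------

_SCHEMA_VERSION = 1


def save_parameters(p: ModelParameters, path: str) -> None:
    doc = {
        "schema_version": _SCHEMA_VERSION,
        "constants": dataclasses.asdict(p.constants),
        "dark_targets": dataclasses.asdict(p.dark),
        "parameters": {
            f.name: getattr(p, f.name)
            for f in dataclasses.fields(p)
            if f.name not in ("constants", "dark")
        },
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def load_parameters(path: str) -> ModelParameters:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if doc.get("schema_version") != _SCHEMA_VERSION:
        raise ValueError("unsupported parameter schema version")
    constants = PhysicalConstants(**doc["constants"])
    dark = DarkTargets(**doc["dark_targets"])
    return ModelParameters(constants=constants, dark=dark, **doc["parameters"])
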