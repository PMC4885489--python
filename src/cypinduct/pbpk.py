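"""Minimal PBPK simulation with dynamic CYP3A4 enzyme turnover.

Structure: gut lumen → enterocyte → portal vein → liver → systemic, for every
compound, with the amounts of active CYP3A4 in liver and gut integrated
jointly with the drug kinetics.  Victim intrinsic clearances scale linearly
with the active-enzyme amount (baseline 1) and are divided by competitive
inhibition terms; enzyme synthesis is stimulated by the perpetrator's unbound
concentration at each site:

    dEnz_H/dt = kdeg_H * Enz_0 * [1 + (Ind_max-1) * I / (IndC_50 + I)]
                - kdeg_H * Enz_H - Enz_H * k_inact * I / (K_I + I)

and analogously for the gut.  Liver extraction follows the well-stirred
model; gut first-pass extraction is E_G = fu_gut*CLu_G / (Q_gut + fu_gut*CLu_G).

Numerical design: the enterocyte and portal-vein pools turn over two orders
of magnitude faster than every other process (Q/V ~ 10^2 /h), so both are
treated as quasi-steady algebraic stages.  This leaves the well-stirred and
gut-extraction closed forms exact, removes the two stiffest modes, and makes
population-scale virtual trials cheap.  The enterocyte concentration that
drives gut-wall induction includes the villous blood supply, so a systemically
available perpetrator keeps stimulating gut CYP3A4 between absorption pulses.

Internal state is in mg and mg/L; interaction terms (IndC_50, Ki_u, K_I) are
evaluated in µM via the molecular weight at each step.  AUC and the pathway
flux integrals used for fm_CYP3A4, F_G and F_H are carried as auxiliary ODE
states, so they share the solver's accuracy.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .calibration import SiteInduction

__all__ = [
    "PathwayClearance",
    "MBIParams",
    "CompoundProfile",
    "SystemParameters",
    "EnzymeState",
    "DoseRegimen",
    "SimOptions",
    "SimulationResult",
    "Simulation",
    "enzyme_rhs",
    "clearance_terms",
    "simulate",
    "extract_metrics",
    "baseline_metrics",
    "mechanistic_static_ratio",
]

logger = logging.getLogger(__name__)

Route = Literal["oral", "iv_bolus", "iv_infusion"]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PathwayClearance:
    """One elimination pathway of a compound, whole-organ scale.

    ``clint`` mode holds an unbound intrinsic clearance in L/h per whole
    organ; ``michaelis_menten`` mode holds (Vmax mg/h, Km_u µM unbound).
    Saturable (Michaelis–Menten) kinetics are supported in the liver;
    gut-wall pathways use the linear mode.
    """

    enzyme: str                    # "CYP3A4" scales with enzyme state; others don't
    site: Literal["liver", "gut"] = "liver"
    clu_int: Optional[float] = None   # L/h whole organ, unbound basis
    vmax: Optional[float] = None      # mg/h whole organ
    km_u: Optional[float] = None      # µM, unbound (corrected for binding)

    def __post_init__(self) -> None:
        linear = self.clu_int is not None
        saturable = self.vmax is not None or self.km_u is not None
        if linear == saturable:
            raise ValueError("exactly one of clu_int or (vmax, km_u) must be given")
        if linear and self.clu_int < 0:
            raise ValueError("clu_int must be >= 0")
        if saturable:
            if self.vmax is None or self.km_u is None:
                raise ValueError("michaelis_menten mode needs both vmax and km_u")
            if self.km_u <= 0:
                raise ValueError("Km_u must be > 0")
            if self.site == "gut":
                raise ValueError("saturable kinetics are only supported in the liver")

    @property
    def mode(self) -> str:
        return "clint" if self.clu_int is not None else "michaelis_menten"


@dataclass(frozen=True)
class MBIParams:
    """Mechanism-based inactivation: loss at rate k_inact * I / (K_I + I)."""

    ki_app_uM: float      # K_I, µM unbound
    kinact_per_h: float   # 1/h

    def __post_init__(self) -> None:
        if self.ki_app_uM <= 0 or self.kinact_per_h < 0:
            raise ValueError("K_I must be > 0 and k_inact >= 0")


@dataclass(frozen=True)
class CompoundProfile:
    """All victim/perpetrator parameters of one compound."""

    name: str
    mw: float                    # g/mol
    fu_p: float                  # unbound fraction in plasma
    bp: float                    # blood:plasma ratio
    fu_gut: float                # unbound fraction in enterocyte
    kp_liver: float              # liver:plasma partition coefficient
    ka: float                    # 1/h first-order absorption
    fa: float                    # fraction absorbed
    vss: float                   # L/kg steady-state volume
    cl_renal: float = 0.0        # L/h (plasma)
    elimination: tuple[PathwayClearance, ...] = ()
    inhibition: dict[str, float] = field(default_factory=dict)  # enzyme -> Ki_u µM
    mbi: Optional[MBIParams] = None
    induction: Optional[SiteInduction] = None  # µM unbound, site-specific

    def __post_init__(self) -> None:
        if not (0 < self.fu_p <= 1):
            raise ValueError(f"{self.name}: fu_p must be in (0, 1]")
        if not (0 < self.fu_gut <= 1):
            raise ValueError(f"{self.name}: fu_gut must be in (0, 1]")
        if self.bp <= 0:
            raise ValueError(f"{self.name}: BP must be > 0")
        if self.mw <= 0:
            raise ValueError(f"{self.name}: MW must be > 0")
        if self.ka < 0:
            raise ValueError(f"{self.name}: ka must be >= 0")
        if not (0 <= self.fa <= 1):
            raise ValueError(f"{self.name}: Fa must be in [0, 1]")
        if self.vss <= 0:
            raise ValueError(f"{self.name}: Vss must be > 0")
        if self.cl_renal < 0:
            raise ValueError(f"{self.name}: CL_renal must be >= 0")
        if self.kp_liver <= 0:
            raise ValueError(f"{self.name}: Kp_liver must be > 0")
        object.__setattr__(self, "elimination", tuple(self.elimination))
        for ki in self.inhibition.values():
            if ki <= 0:
                raise ValueError(f"{self.name}: Ki_u must be > 0")

    @property
    def fu_b(self) -> float:
        """Unbound fraction in blood, fu_p / B:P."""
        return self.fu_p / self.bp

    def liver_pathways(self) -> tuple[PathwayClearance, ...]:
        return tuple(p for p in self.elimination if p.site == "liver")

    def gut_pathways(self) -> tuple[PathwayClearance, ...]:
        return tuple(p for p in self.elimination if p.site == "gut")


@dataclass(frozen=True)
class SystemParameters:
    """Minimal-PBPK system constants (70-kg reference adult)."""

    q_h: float = 90.0       # hepatic blood flow, L/h
    q_pv: float = 70.0      # portal vein blood flow, L/h
    q_gut: float = 18.0     # villous flow of the gut-extraction model, L/h
    v_liver: float = 1.7    # L
    v_portal: float = 1.0   # L (reported concentrations only; pool is quasi-steady)
    v_ent: float = 0.5      # L (reported concentrations only; pool is quasi-steady)
    bw: float = 70.0        # kg
    kdeg_h: float = 0.0193  # 1/h, hepatic CYP3A4 degradation
    kdeg_g: float = 0.03    # 1/h, gut CYP3A4 degradation

    def __post_init__(self) -> None:
        for name in ("q_h", "q_pv", "q_gut", "v_liver", "v_portal", "v_ent",
                     "bw", "kdeg_h", "kdeg_g"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.q_pv > self.q_h:
            raise ValueError("Q_pv must not exceed Q_h")


@dataclass
class EnzymeState:
    """Active CYP3A4 amounts, relative units (baseline 1)."""

    enz_act_h: float = 1.0
    enz_act_g: float = 1.0
    enz_0_h: float = 1.0
    enz_0_g: float = 1.0
    kdeg_h: float = 0.0193
    kdeg_g: float = 0.03

    def __post_init__(self) -> None:
        if self.enz_act_h < 0 or self.enz_act_g < 0:
            raise ValueError("enzyme amounts must be >= 0")
        if self.kdeg_h <= 0 or self.kdeg_g <= 0:
            raise ValueError("kdeg must be > 0")


@dataclass(frozen=True)
class DoseRegimen:
    """One compound's dosing schedule."""

    compound: str
    dose: float                 # mg, or mg/kg when per_kg
    route: Route = "oral"
    interval_h: float = 24.0
    n_doses: int = 1
    start_time_h: float = 0.0
    per_kg: bool = False
    infusion_duration_h: float = 0.0

    def __post_init__(self) -> None:
        if self.dose <= 0:
            raise ValueError("dose must be > 0")
        if self.n_doses < 1:
            raise ValueError("n_doses must be >= 1")
        if self.n_doses > 1 and self.interval_h <= 0:
            raise ValueError("interval must be > 0 for multiple doses")
        if self.route not in ("oral", "iv_bolus", "iv_infusion"):
            raise ValueError(f"unknown route {self.route!r}")
        if self.route == "iv_infusion" and self.infusion_duration_h <= 0:
            raise ValueError("iv_infusion needs a positive duration")

    def dose_times(self) -> np.ndarray:
        return self.start_time_h + self.interval_h * np.arange(self.n_doses)

    @property
    def last_dose_time(self) -> float:
        return self.start_time_h + self.interval_h * (self.n_doses - 1)

    def resolved_dose(self, bw: float) -> float:
        return self.dose * bw if self.per_kg else self.dose


@dataclass(frozen=True)
class SimOptions:
    rtol: float = 1e-6
    atol: float = 1e-9
    method: str = "LSODA"
    gut_driver: Literal["enterocyte", "portal"] = "enterocyte"
    horizon_h: Optional[float] = None
    n_half_lives: float = 5.0
    points_per_segment: int = 12
    #: compound name -> (I_liver µM unbound, I_gut µM unbound); the compound is
    #: held at constant unbound exposure instead of being integrated.
    clamped: dict[str, tuple[float, float]] = field(default_factory=dict)
    initial_enzymes: tuple[float, float] = (1.0, 1.0)
    #: compound name -> (A_lumen, A_liver, A_systemic) carried over from a
    #: previous simulation stage.
    initial_amounts: dict[str, tuple[float, float, float]] = field(default_factory=dict)
    start_time_h: float = 0.0
    #: compound names whose AUC/flux integrals are carried as ODE states;
    #: None tracks every compound.  Untracked compounds keep full kinetics
    #: but report no exposure metrics (used for perpetrator pretreatment).
    track: Optional[tuple[str, ...]] = None


@dataclass
class SimulationResult:
    """Time courses and summary exposure metrics for one compound."""

    name: str
    t: np.ndarray
    conc_plasma: np.ndarray        # systemic plasma, mg/L
    conc_liver: np.ndarray         # liver tissue, mg/L
    conc_portal_plasma: np.ndarray
    conc_enterocyte: np.ndarray    # total enterocyte (quasi-steady), mg/L
    enz_h: np.ndarray
    enz_g: np.ndarray
    mw: float
    auc_0_t: float                 # mg/L·h over the simulated window
    auc_0_inf: Optional[float]
    auc_tail_ok: bool
    cmax: float
    fg: Optional[float]            # fraction escaping gut wall (oral dosing)
    fh: Optional[float]
    fm_cyp3a4: Optional[float]
    dosed: bool = True

    def conc_plasma_uM(self) -> np.ndarray:
        return self.conc_plasma * 1000.0 / self.mw


@dataclass
class Simulation:
    """Container for a completed multi-compound run."""

    results: dict[str, SimulationResult]
    final_enzymes: tuple[float, float]
    final_amounts: dict[str, tuple[float, float, float]]
    t_end: float
    t: np.ndarray = field(default_factory=lambda: np.empty(0))
    enz_h: np.ndarray = field(default_factory=lambda: np.empty(0))
    enz_g: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __getitem__(self, name: str) -> SimulationResult:
        return self.results[name]


# ---------------------------------------------------------------------------
# elemental operations (also used standalone in tests)
# ---------------------------------------------------------------------------

def enzyme_rhs(
    state: EnzymeState,
    i_liver_u: float,
    i_gut_u: float,
    induction: Optional[SiteInduction],
    mbi: Optional[MBIParams] = None,
) -> tuple[float, float]:
    """Turnover derivatives (d/dt) of active liver and gut CYP3A4.

    ``i_liver_u`` / ``i_gut_u`` are unbound perpetrator concentrations (µM)
    at each site.  Synthesis is zero-order, stimulated by induction;
    degradation is first-order; mechanism-based inactivation adds a loss
    proportional to the active amount.
    """
    if i_liver_u < 0 or i_gut_u < 0:
        raise ValueError("perpetrator concentrations must be >= 0")
    stim_h = stim_g = 0.0
    if induction is not None:
        stim_h = (induction.ind_max_liver - 1.0) * i_liver_u / (induction.indc50_liver + i_liver_u) \
            if i_liver_u > 0 else 0.0
        stim_g = (induction.ind_max_gut - 1.0) * i_gut_u / (induction.indc50_gut + i_gut_u) \
            if i_gut_u > 0 else 0.0
    inact_h = inact_g = 0.0
    if mbi is not None:
        inact_h = mbi.kinact_per_h * i_liver_u / (mbi.ki_app_uM + i_liver_u)
        inact_g = mbi.kinact_per_h * i_gut_u / (mbi.ki_app_uM + i_gut_u)
    dh = state.kdeg_h * state.enz_0_h * (1.0 + stim_h) - state.kdeg_h * state.enz_act_h \
        - state.enz_act_h * inact_h
    dg = state.kdeg_g * state.enz_0_g * (1.0 + stim_g) - state.kdeg_g * state.enz_act_g \
        - state.enz_act_g * inact_g
    return dh, dg


def clearance_terms(
    victim: CompoundProfile,
    enzymes: EnzymeState,
    i_liver_u: float = 0.0,
    i_gut_u: float = 0.0,
    ki_u: Optional[dict[str, float]] = None,
    s_u_liver_mgL: float = 0.0,
) -> tuple[float, float]:
    """Whole-organ unbound intrinsic clearances (liver, gut) of a victim.

    Each pathway contributes CLu_int (or Vmax/(Km_u + S_u)) scaled by the
    active-enzyme amount for CYP3A4-mediated pathways (factor 1 otherwise)
    and divided by a competitive-inhibition term 1 + I_u/Ki_u; the divisor is
    1 when no Ki is supplied for the mediating enzyme.
    """
    ki_u = ki_u or {}
    known = {"CYP3A4", "other", "additional-HLM"}
    for p in victim.elimination:
        if p.enzyme not in known:
            raise ValueError(f"unknown enzyme {p.enzyme!r}")
    fold_h = enzymes.enz_act_h / enzymes.enz_0_h
    fold_g = enzymes.enz_act_g / enzymes.enz_0_g
    clu_h = 0.0
    for p in victim.liver_pathways():
        scale = fold_h if p.enzyme == "CYP3A4" else 1.0
        div = 1.0 + (i_liver_u / ki_u[p.enzyme] if p.enzyme in ki_u else 0.0)
        if p.mode == "clint":
            clu_h += p.clu_int * scale / div
        else:
            km_mgL = p.km_u * victim.mw / 1000.0
            clu_h += p.vmax * scale / (km_mgL * div + s_u_liver_mgL)
    clu_g = 0.0
    for p in victim.gut_pathways():
        scale = fold_g if p.enzyme == "CYP3A4" else 1.0
        div = 1.0 + (i_gut_u / ki_u[p.enzyme] if p.enzyme in ki_u else 0.0)
        clu_g += p.clu_int * scale / div
    return clu_h, clu_g


def baseline_metrics(
    profile: CompoundProfile, system: SystemParameters,
    enzyme_fold_h: float = 1.0, enzyme_fold_g: float = 1.0,
) -> dict[str, float]:
    """Closed-form steady-enzyme disposition metrics (well-stirred liver).

    Returns hepatic/renal/total plasma clearances, blood hepatic clearance,
    F_H, F_G, fm_CYP3A4 and the terminal half-life estimate used to size
    simulation horizons.
    """
    es = EnzymeState(enz_act_h=enzyme_fold_h, enz_act_g=enzyme_fold_g,
                     kdeg_h=system.kdeg_h, kdeg_g=system.kdeg_g)
    clu_h, clu_g = clearance_terms(profile, es)
    fub = profile.fu_b
    cl_h_blood = system.q_h * fub * clu_h / (system.q_h + fub * clu_h) if clu_h > 0 else 0.0
    f_h = system.q_h / (system.q_h + fub * clu_h) if clu_h > 0 else 1.0
    f_g = system.q_gut / (system.q_gut + profile.fu_gut * clu_g) if clu_g > 0 else 1.0
    cl_h_plasma = cl_h_blood * profile.bp
    cl_total = cl_h_plasma + profile.cl_renal
    clu3a4_h = sum(p.clu_int if p.mode == "clint" else p.vmax / (p.km_u * profile.mw / 1000.0)
                   for p in profile.liver_pathways() if p.enzyme == "CYP3A4")
    fm = 0.0
    if cl_total > 0 and clu_h > 0:
        fm = (clu3a4_h * enzyme_fold_h / clu_h) * cl_h_plasma / cl_total
    v_sys = profile.vss * system.bw
    kel = cl_total / v_sys if cl_total > 0 else 0.0
    return {
        "cl_hepatic_blood": cl_h_blood,
        "cl_hepatic_plasma": cl_h_plasma,
        "cl_renal": profile.cl_renal,
        "cl_total_plasma": cl_total,
        "f_h": f_h,
        "f_g": f_g,
        "fm_cyp3a4": fm,
        "t_half_h": math.log(2) / kel if kel > 0 else math.inf,
    }


def mechanistic_static_ratio(
    victim: CompoundProfile,
    system: SystemParameters,
    fold_h: float,
    fold_g: float,
    route: Route = "oral",
) -> float:
    """Static net-effect reciprocal AUC ratio (control/induced).

    Built from the same well-stirred/gut-extraction closed forms as the
    dynamic model, with the enzyme fold-changes held fixed:
    AUC_po = Fa*F_G*F_H*D/CL_total, AUC_iv = D/CL_total.
    """
    base = baseline_metrics(victim, system)
    ind = baseline_metrics(victim, system, enzyme_fold_h=fold_h, enzyme_fold_g=fold_g)
    if route in ("iv_bolus", "iv_infusion"):
        return ind["cl_total_plasma"] / base["cl_total_plasma"]
    num = base["f_g"] * base["f_h"] / base["cl_total_plasma"]
    den = ind["f_g"] * ind["f_h"] / ind["cl_total_plasma"]
    return num / den


# ---------------------------------------------------------------------------
# compiled joint system
# ---------------------------------------------------------------------------

_N_DYN = 3   # A_lumen, A_liver, A_systemic
_N_AUX = 7   # auc, J_3a4, J_hep, J_renal, J_gut_met, J_gut_escape, J_liver_in


class _Compiled:
    """Pre-resolved constants and index maps for the joint ODE system."""

    def __init__(self, compounds, system, options):
        self.system = system
        self.options = options
        self.dynamic = [c for c in compounds if c.name not in options.clamped]
        self.clamped = [(c, options.clamped[c.name]) for c in compounds
                        if c.name in options.clamped]
        self.names = [c.name for c in self.dynamic]
        track = options.track
        self.tracked = [track is None or c.name in track for c in self.dynamic]
        self.offsets = []
        pos = 2
        for aux in self.tracked:
            self.offsets.append(pos)
            pos += _N_DYN + (_N_AUX if aux else 0)
        self.n_states = pos
        self.conv = [1000.0 / c.mw for c in self.dynamic]
        self.v_sys = [c.vss * system.bw for c in self.dynamic]
        # inducer/MBI sources: (dynamic index | None for clamped, params…)
        self.inducers = []
        self.inactivators = []
        for i, c in enumerate(self.dynamic):
            if c.induction is not None:
                self.inducers.append((i, None, c.induction))
            if c.mbi is not None:
                self.inactivators.append((i, None, c.mbi))
        for c, (il, ig) in self.clamped:
            if c.induction is not None:
                self.inducers.append((None, (il, ig), c.induction))
            if c.mbi is not None:
                self.inactivators.append((None, (il, ig), c.mbi))
        # competitive inhibition: per victim pathway enzyme, list of sources
        self.inhibitor_sources = []  # (dyn index | None, (il, ig) | None, {enzyme: ki})
        for i, c in enumerate(self.dynamic):
            if c.inhibition:
                self.inhibitor_sources.append((i, None, c.inhibition))
        for c, (il, ig) in self.clamped:
            if c.inhibition:
                self.inhibitor_sources.append((None, (il, ig), c.inhibition))
        self.infusion_rate = [0.0] * len(self.dynamic)  # mg/h, managed per segment

    def index(self, name: str) -> int:
        return self.names.index(name)


def _make_rhs(model: _Compiled):
    sys_ = model.system
    dynamic = model.dynamic
    offsets = model.offsets
    conv = model.conv
    v_sys = model.v_sys
    gut_driver_ent = model.options.gut_driver == "enterocyte"

    # flatten per-compound constants
    consts = []
    for c in dynamic:
        lin3a4_h = sum(p.clu_int for p in c.liver_pathways()
                       if p.mode == "clint" and p.enzyme == "CYP3A4")
        linoth_h = sum(p.clu_int for p in c.liver_pathways()
                       if p.mode == "clint" and p.enzyme != "CYP3A4")
        mm_h = [(p.vmax, p.km_u * c.mw / 1000.0, p.enzyme == "CYP3A4")
                for p in c.liver_pathways() if p.mode == "michaelis_menten"]
        lin3a4_g = sum(p.clu_int for p in c.gut_pathways() if p.enzyme == "CYP3A4")
        linoth_g = sum(p.clu_int for p in c.gut_pathways() if p.enzyme != "CYP3A4")
        consts.append((c.ka, c.fa, c.fu_p, c.bp, c.fu_gut, c.kp_liver, c.cl_renal,
                       lin3a4_h, linoth_h, mm_h, lin3a4_g, linoth_g))

    # inhibition: does any victim pathway have an inhibitor? resolve Ki lookups once
    inh = model.inhibitor_sources

    def rhs(t, y):
        enz_h, enz_g = y[0], y[1]
        if enz_h < 0:
            enz_h = 0.0
        if enz_g < 0:
            enz_g = 0.0
        dy = np.zeros_like(y)

        # site concentrations of every dynamic compound
        site = []
        for i, c in enumerate(dynamic):
            ka, fa, fu_p, bp, fu_gut, kp, clr, l3h, loh, mmh, l3g, log_ = consts[i]
            off = offsets[i]
            a_lum, a_liv, a_sys = y[off], y[off + 1], y[off + 2]
            c_sys_p = a_sys / v_sys[i]
            c_sys_b = bp * c_sys_p
            c_liv = a_liv / sys_.v_liver
            cu_liv = fu_p * c_liv / kp
            clu_g_base = l3g * enz_g + log_  # enzyme-scaled, pre-inhibition
            c_ent = (ka * fa * a_lum + sys_.q_gut * c_sys_b) / (
                sys_.q_gut + fu_gut * clu_g_base)
            c_pv_b = c_sys_b + sys_.q_gut * c_ent / sys_.q_pv
            cu_gut = fu_gut * c_ent if gut_driver_ent else fu_p * c_pv_b / bp
            site.append((cu_liv * conv[i], cu_gut * conv[i], c_sys_p, c_sys_b,
                         c_liv, cu_liv, c_ent, c_pv_b))

        # enzyme turnover driven by inducer/inactivator site concentrations
        stim_h = stim_g = inact_h = inact_g = 0.0
        for idx, const_iu, indn in model.inducers:
            iu_l, iu_g = (site[idx][0], site[idx][1]) if idx is not None else const_iu
            stim_h += (indn.ind_max_liver - 1.0) * iu_l / (indn.indc50_liver + iu_l)
            stim_g += (indn.ind_max_gut - 1.0) * iu_g / (indn.indc50_gut + iu_g)
        for idx, const_iu, mb in model.inactivators:
            iu_l, iu_g = (site[idx][0], site[idx][1]) if idx is not None else const_iu
            inact_h += mb.kinact_per_h * iu_l / (mb.ki_app_uM + iu_l)
            inact_g += mb.kinact_per_h * iu_g / (mb.ki_app_uM + iu_g)
        dy[0] = sys_.kdeg_h * (1.0 + stim_h) - sys_.kdeg_h * enz_h - enz_h * inact_h
        dy[1] = sys_.kdeg_g * (1.0 + stim_g) - sys_.kdeg_g * enz_g - enz_g * inact_g

        for i, c in enumerate(dynamic):
            ka, fa, fu_p, bp, fu_gut, kp, clr, l3h, loh, mmh, l3g, log_ = consts[i]
            off = offsets[i]
            a_lum = y[off]
            iu_l, iu_g, c_sys_p, c_sys_b, c_liv, cu_liv, c_ent, c_pv_b = site[i]

            # competitive inhibition divisors for this victim's 3A4 pathways
            div_h3 = div_g3 = div_ho = div_go = 1.0
            for j, const_iu, kimap in inh:
                if j == i:
                    continue
                il, ig = (site[j][0], site[j][1]) if j is not None else const_iu
                if "CYP3A4" in kimap:
                    div_h3 += il / kimap["CYP3A4"]
                    div_g3 += ig / kimap["CYP3A4"]
                if "other" in kimap:
                    div_ho += il / kimap["other"]
                    div_go += ig / kimap["other"]

            clu_h = l3h * enz_h / div_h3 + loh / div_ho
            flux3a4 = l3h * enz_h / div_h3 * cu_liv
            for vmax, km_mgL, is3a4 in mmh:
                scale = enz_h if is3a4 else 1.0
                d = div_h3 if is3a4 else div_ho
                contrib = vmax * scale / (km_mgL * d + cu_liv)
                clu_h += contrib
                if is3a4:
                    flux3a4 += contrib * cu_liv
            clu_g = l3g * enz_g / div_g3 + log_ / div_go

            # quasi-steady enterocyte mass balance for the orally absorbed dose
            abs_flux = ka * fa * a_lum
            c_ent_fp = abs_flux / (sys_.q_gut + fu_gut * clu_g)  # first-pass pool
            gut_met = fu_gut * clu_g * c_ent_fp
            gut_escape = sys_.q_gut * c_ent_fp

            hep_in = sys_.q_pv * (c_sys_b + gut_escape / sys_.q_pv) \
                + (sys_.q_h - sys_.q_pv) * c_sys_b
            hep_out = sys_.q_h * (c_liv / kp) * bp
            hep_met = clu_h * cu_liv
            renal = clr * c_sys_p

            dy[off] = -ka * a_lum
            dy[off + 1] = hep_in - hep_out - hep_met
            dy[off + 2] = hep_out - sys_.q_h * c_sys_b - renal + model.infusion_rate[i]
            if model.tracked[i]:
                dy[off + 3] = c_sys_p          # AUC
                dy[off + 4] = flux3a4          # hepatic CYP3A4 flux
                dy[off + 5] = hep_met          # hepatic total flux
                dy[off + 6] = renal
                dy[off + 7] = gut_met
                dy[off + 8] = gut_escape
                dy[off + 9] = hep_in
        return dy

    return rhs


# ---------------------------------------------------------------------------
# event-driven integration
# ---------------------------------------------------------------------------

def _auto_horizon(compounds, regimens, system, options) -> float:
    t_end = options.start_time_h
    for reg in regimens:
        prof = next(c for c in compounds if c.name == reg.compound)
        t_half = baseline_metrics(prof, system)["t_half_h"]
        if not math.isfinite(t_half):
            t_half = 24.0
        t_end = max(t_end, reg.last_dose_time + reg.infusion_duration_h
                    + options.n_half_lives * t_half)
    return t_end


def simulate(
    compounds: Sequence[CompoundProfile],
    regimens: Sequence[DoseRegimen],
    system: SystemParameters = SystemParameters(),
    options: SimOptions = SimOptions(),
) -> Simulation:
    """Integrate the joint victim/perpetrator/enzyme system over a schedule.

    Dosing is handled by state re-initialization at exact event times (oral
    boluses enter the gut lumen, i.v. boluses the systemic compartment,
    infusions as piecewise-constant rates).  Autoinduction emerges when a
    perpetrator's own elimination is CYP3A4-mediated, because every
    CYP3A4 pathway of every compound scales with the same enzyme states.
    """
    compounds = list(compounds)
    names = {c.name for c in compounds}
    for reg in regimens:
        if reg.compound not in names:
            raise ValueError(f"regimen references unknown compound {reg.compound!r}")
        if reg.compound in options.clamped:
            raise ValueError(f"clamped compound {reg.compound!r} cannot be dosed")
    model = _Compiled(compounds, system, options)
    rhs = _make_rhs(model)

    t0 = options.start_time_h
    horizon = options.horizon_h if options.horizon_h is not None \
        else _auto_horizon(compounds, regimens, system, options)
    if horizon <= t0:
        raise ValueError("simulation horizon must exceed the start time")

    # events: (time, kind, payload)
    events: list[tuple[float, str, tuple]] = []
    for reg in regimens:
        amount = reg.resolved_dose(system.bw)
        for td in reg.dose_times():
            if td < t0 - 1e-9 or td > horizon:
                continue
            i = model.index(reg.compound)
            if reg.route == "oral":
                events.append((td, "bolus", (i, 0, amount)))
            elif reg.route == "iv_bolus":
                events.append((td, "bolus", (i, 2, amount)))
            else:
                rate = amount / reg.infusion_duration_h
                events.append((td, "rate_on", (i, rate)))
                events.append((td + reg.infusion_duration_h, "rate_off", (i, rate)))
    boundaries = sorted({t0, horizon, *(e[0] for e in events)})

    y = np.zeros(model.n_states)
    y[0], y[1] = options.initial_enzymes
    for name, (a_lum, a_liv, a_sys) in options.initial_amounts.items():
        off = model.offsets[model.index(name)]
        y[off], y[off + 1], y[off + 2] = a_lum, a_liv, a_sys

    ts: list[np.ndarray] = []
    ys: list[np.ndarray] = []
    for ta, tb in zip(boundaries[:-1], boundaries[1:]):
        for te, kind, payload in events:
            if abs(te - ta) < 1e-9:
                if kind == "bolus":
                    i, slot, amount = payload
                    y[model.offsets[i] + slot] += amount
                elif kind == "rate_on":
                    model.infusion_rate[payload[0]] += payload[1]
                else:
                    model.infusion_rate[payload[0]] -= payload[1]
        if tb - ta < 1e-9:
            continue
        t_eval = np.linspace(ta, tb, max(options.points_per_segment, 2))
        sol = solve_ivp(rhs, (ta, tb), y, method=options.method,
                        rtol=options.rtol, atol=options.atol, t_eval=t_eval)
        if not sol.success:
            raise RuntimeError(f"ODE integration failed on [{ta}, {tb}]: {sol.message}")
        y = sol.y[:, -1].copy()
        dyn_idx = [0, 1] + [off + k for off in model.offsets for k in range(_N_DYN)]
        neg = y[dyn_idx]
        if np.any(neg < -1e-6):
            raise RuntimeError(f"negative state beyond tolerance at t={tb}: min={neg.min()}")
        np.clip(y, 0.0, None, out=y)
        ts.append(sol.t)
        ys.append(sol.y)
    t_all = np.concatenate(ts)
    y_all = np.concatenate(ys, axis=1)

    dosed = {reg.compound for reg in regimens}
    results: dict[str, SimulationResult] = {}
    final_amounts: dict[str, tuple[float, float, float]] = {}
    for i, c in enumerate(model.dynamic):
        off = model.offsets[i]
        results[c.name] = _summarize(c, i, off, model, system, t_all, y_all, y,
                                     c.name in dosed)
        final_amounts[c.name] = (float(y[off]), float(y[off + 1]), float(y[off + 2]))
    return Simulation(results=results, final_enzymes=(float(y[0]), float(y[1])),
                      final_amounts=final_amounts, t_end=float(t_all[-1]),
                      t=t_all, enz_h=y_all[0], enz_g=y_all[1])


def _summarize(c, i, off, model, system, t_all, y_all, y_end, dosed) -> SimulationResult:
    v_sys = model.v_sys[i]
    # clip solver interpolation noise at zero
    conc_p = np.clip(y_all[off + 2] / v_sys, 0.0, None)
    conc_liv = np.clip(y_all[off + 1] / system.v_liver, 0.0, None)
    c_sys_b = c.bp * conc_p
    clu_g_lin = sum(p.clu_int for p in c.gut_pathways())
    c_ent = np.clip((c.ka * c.fa * y_all[off] + system.q_gut * c_sys_b) / (
        system.q_gut + c.fu_gut * clu_g_lin), 0.0, None)
    c_pv_b = c_sys_b + system.q_gut * c_ent / system.q_pv
    tracked = model.tracked[i]
    auc = float(y_end[off + 3]) if tracked else 0.0
    if tracked:
        j3a4, jhep, jren = (float(y_end[off + k]) for k in (4, 5, 6))
        jgm, jge, jin = (float(y_end[off + k]) for k in (7, 8, 9))
        fm = j3a4 / (jhep + jren) if (jhep + jren) > 0 else None
        fg = jge / (jge + jgm) if (jge + jgm) > 0 else None
        fh = 1.0 - jhep / jin if jin > 0 else None
    else:
        fm = fg = fh = None

    auc_inf: Optional[float] = None
    tail_ok = False
    if tracked and dosed and auc > 0:
        c_last = float(conc_p[-1])
        fold_h = float(y_end[0])
        fold_g = float(y_end[1])
        m = baseline_metrics(c, system, enzyme_fold_h=fold_h, enzyme_fold_g=fold_g)
        # terminal phase sees the systemic plus liver (plasma-referenced) volume
        kz = m["cl_total_plasma"] / (v_sys + c.kp_liver * system.v_liver)
        if kz > 0 and c_last >= 0:
            auc_inf = auc + c_last / kz
            tail_ok = c_last / kz <= 0.2 * auc_inf
            if not tail_ok:
                logger.warning("AUC tail for %s is %.0f%% of total; AUC_0_inf flagged",
                               c.name, 100 * c_last / kz / auc_inf)
    return SimulationResult(
        name=c.name, t=t_all, conc_plasma=conc_p, conc_liver=conc_liv,
        conc_portal_plasma=c_pv_b / c.bp, conc_enterocyte=c_ent,
        enz_h=y_all[0], enz_g=y_all[1], mw=c.mw,
        auc_0_t=auc, auc_0_inf=auc_inf, auc_tail_ok=tail_ok,
        cmax=float(np.max(conc_p)) if conc_p.size else 0.0,
        fg=fg, fh=fh, fm_cyp3a4=fm, dosed=dosed,
    )


def extract_metrics(
    result: SimulationResult,
    interval: Optional[tuple[float, float]] = None,
) -> dict[str, Optional[float]]:
    """AUC (trapezoid + terminal tail), C_max, F_G and fm over an interval.

    The trapezoidal AUC on the stored grid cross-checks the solver-integrated
    value; the infinite tail uses the terminal log-linear phase and is flagged
    (``auc_tail_identifiable``) when the slope cannot be estimated.
    """
    t, cp = result.t, result.conc_plasma
    if interval is not None:
        lo, hi = interval
        mask = (t >= lo) & (t <= hi)
        if not mask.any():
            raise ValueError("profile does not cover the requested interval")
        t, cp = t[mask], cp[mask]
    auc_t = float(np.trapezoid(cp, t))
    lam_z, identifiable = _terminal_slope(t, cp)
    auc_inf = auc_t + float(cp[-1]) / lam_z if identifiable else None
    return {
        "auc_0_t": auc_t,
        "auc_0_inf": auc_inf,
        "auc_tail_identifiable": identifiable,
        "cmax": float(np.max(cp)) if cp.size else 0.0,
        "fg": result.fg,
        "fh": result.fh,
        "fm_cyp3a4": result.fm_cyp3a4,
    }


def _terminal_slope(t: np.ndarray, cp: np.ndarray) -> tuple[float, bool]:
    pos = cp > 0
    if pos.sum() < 4:
        return math.nan, False
    t_pos, c_pos = t[pos], cp[pos]
    n_tail = max(4, len(t_pos) // 5)
    tt, cc = t_pos[-n_tail:], np.log(c_pos[-n_tail:])
    if tt[-1] - tt[0] <= 0:
        return math.nan, False
    slope = np.polyfit(tt, cc, 1)[0]
    if slope >= -1e-12:
        return math.nan, False
    return float(-slope), True
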