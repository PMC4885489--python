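"""Synthetic inputs with known ground truth: induction assays, compound
profiles, and observed-study tables.

The induction generator emulates a multi-donor cryopreserved-hepatocyte
experiment: donor-level (Ind_max, IndC_50) drawn log-normally around the
study truth (on Ind_max − 1 so Ind_max ≥ 1 by construction), fold responses
evaluated on the assay concentration grid and perturbed by multiplicative
log-normal residual noise, with the vehicle-control fold anchored near 1.
Default donor spreads follow the observed four-donor rifampicin-activity
variability (SD/mean ≈ 0.34 on Ind_max, ≈ 0.33 on IndC_50).

Compound archetypes are curated, internally consistent minimal-PBPK profiles
(orally dosed 70-kg adult conventions).  The victim library targets each
probe substrate's literature fm_CYP3A4 and F_G by back-calculating pathway
intrinsic clearances from the well-stirred and gut-extraction closed forms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

from .calibration import SiteInduction
from .induction import InductionDataset
from .pbpk import (
    CompoundProfile,
    DoseRegimen,
    PathwayClearance,
    SimOptions,
    SystemParameters,
)
from .trial import CVConfig, DDIStudyDesign

__all__ = [
    "SyntheticInductionSpec",
    "SyntheticStudySpec",
    "TABLE1_GRIDS",
    "make_induction_dataset",
    "make_compound_profile",
    "profile_from_targets",
    "victim_profile",
    "VICTIM_LIBRARY",
    "make_study_table",
]

#: assay concentration grids (µM) per prototypical inducer
TABLE1_GRIDS: dict[str, tuple[float, ...]] = {
    "rifampicin": (0.03, 0.1, 0.3, 1, 3, 10, 30),
    "carbamazepine": (1, 3, 10, 30, 100, 300, 1000),
    "phenytoin": (1, 3, 10, 30, 100, 300, 1000),
    "phenobarbital": (10, 30, 100, 300, 1000, 2000, 3000),
    "efavirenz": (0.1, 0.3, 1, 2, 3, 10, 30),
    "nifedipine": (0.03, 1, 2, 3, 10, 30, 100),
}


@dataclass(frozen=True)
class SyntheticInductionSpec:
    inducer: str = "rifampicin"
    endpoint: str = "activity"
    ind_max: float = 22.7
    indc50: float = 0.30     # µM
    hill: float = 1.0
    grid: tuple[float, ...] = TABLE1_GRIDS["rifampicin"]
    n_donors: int = 4
    donor_cv_ind_max: float = 0.34   # log-normal CV on Ind_max - 1 across donors
    donor_cv_indc50: float = 0.33
    noise_cv: float = 0.15           # multiplicative residual on fold values
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ind_max < 1 or self.indc50 <= 0 or self.hill <= 0:
            raise ValueError("truth must satisfy Ind_max >= 1, IndC_50 > 0, hill > 0")
        if min(self.donor_cv_ind_max, self.donor_cv_indc50, self.noise_cv) < 0:
            raise ValueError("CVs must be >= 0")
        if self.n_donors < 1:
            raise ValueError("n_donors must be >= 1")


def _lognormal_mult(rng: np.random.Generator, cv: float, size=None):
    """Multiplicative log-normal factor with mean 1 and the given CV."""
    if cv == 0:
        return np.ones(size) if size else 1.0
    sigma = math.sqrt(math.log1p(cv * cv))
    return np.exp(rng.normal(-0.5 * sigma * sigma, sigma, size))


def make_induction_dataset(spec: SyntheticInductionSpec) -> list[InductionDataset]:
    """One synthetic induction dataset per donor, deterministic in the seed.

    Donor truths are mean-1 log-normal perturbations of the spec truth, so
    arithmetic donor means converge to the spec values; fold responses carry
    multiplicative residual noise and stay positive by construction.
    """
    rng = np.random.default_rng(spec.seed)
    conc = np.asarray(spec.grid, dtype=float)
    out = []
    for d in range(spec.n_donors):
        emax_d = (spec.ind_max - 1.0) * _lognormal_mult(rng, spec.donor_cv_ind_max)
        c50_d = spec.indc50 * _lognormal_mult(rng, spec.donor_cv_indc50)
        ch = np.power(conc, spec.hill)
        fold = 1.0 + emax_d * ch / (c50_d ** spec.hill + ch)
        fold = fold * _lognormal_mult(rng, spec.noise_cv, size=conc.size)
        out.append(InductionDataset(
            inducer=spec.inducer, donor_id=f"donor{d + 1}", endpoint=spec.endpoint,
            concentrations=conc, fold_response=fold))
    return out


# ---------------------------------------------------------------------------
# compound archetypes
# ---------------------------------------------------------------------------

def profile_from_targets(
    name: str,
    mw: float,
    fu_p: float,
    bp: float,
    cl_iv_plasma: float,     # L/h, systemic plasma clearance
    vss: float,              # L/kg
    fm_cyp3a4: float,
    f_g: float,
    ka: float = 1.5,
    fa: float = 1.0,
    fu_gut: float = 1.0,
    kp_liver: float = 2.0,
    cl_renal: float = 0.0,
    system: SystemParameters = SystemParameters(),
    induction: Optional[SiteInduction] = None,
    inhibition: Optional[dict] = None,
) -> CompoundProfile:
    """Back-calculate pathway clearances hitting target fm_CYP3A4 and F_G.

    Hepatic CLu_int is recovered from the well-stirred model at the target
    i.v. plasma clearance and split between a CYP3A4 and an "other" pathway
    so that the CYP3A4 share of total (hepatic + renal) clearance equals
    ``fm_cyp3a4``; the gut-wall CYP3A4 CLu_int is set from the target F_G.
    """
    cl_h_plasma = cl_iv_plasma - cl_renal
    if cl_h_plasma < 0:
        raise ValueError("renal clearance exceeds total clearance")
    fu_b = fu_p / bp
    pathways = []
    if cl_h_plasma > 0:
        cl_b = cl_h_plasma / bp
        if cl_b >= system.q_h:
            raise ValueError(
                f"{name}: hepatic blood clearance {cl_b:.1f} exceeds liver blood flow")
        clu_h = system.q_h * cl_b / (fu_b * (system.q_h - cl_b))
        share = fm_cyp3a4 * cl_iv_plasma / cl_h_plasma
        if not (0 <= share <= 1):
            raise ValueError(f"{name}: fm_CYP3A4 target incompatible with renal clearance")
        if share > 0:
            pathways.append(PathwayClearance("CYP3A4", "liver", clu_int=clu_h * share))
        if share < 1:
            pathways.append(PathwayClearance("other", "liver", clu_int=clu_h * (1 - share)))
    if not (0 < f_g <= 1):
        raise ValueError("F_G target must be in (0, 1]")
    if f_g < 1:
        clu_g = system.q_gut * (1 - f_g) / (f_g * fu_gut)
        pathways.append(PathwayClearance("CYP3A4", "gut", clu_int=clu_g))
    return CompoundProfile(
        name=name, mw=mw, fu_p=fu_p, bp=bp, fu_gut=fu_gut, kp_liver=kp_liver,
        ka=ka, fa=fa, vss=vss, cl_renal=cl_renal, elimination=tuple(pathways),
        induction=induction, inhibition=inhibition or {})


#: curated example profiles of the CYP3A4 probe substrates
#: (mw, fu_p, bp, cl_iv_plasma L/h, vss L/kg, fm_3A4, F_G, ka 1/h, cl_renal)
_VICTIM_PARAMS: dict[str, tuple] = {
    "midazolam":   (325.8, 0.032, 0.66, 27.0, 1.0, 0.93, 0.50, 3.0, 0.0),
    "alfentanil":  (416.5, 0.10, 0.63, 17.5, 0.50, 0.92, 0.85, 2.0, 0.0),
    "nifedipine":  (346.3, 0.040, 0.68, 35.0, 0.80, 0.91, 0.75, 2.5, 0.0),
    "alprazolam":  (308.8, 0.32, 0.78, 3.8, 0.75, 0.80, 0.95, 1.5, 0.4),
    "simvastatin": (418.6, 0.020, 0.60, 30.0, 1.5, 0.99, 0.66, 1.0, 0.0),
    "zolpidem":    (307.4, 0.080, 0.76, 15.0, 0.54, 0.60, 0.80, 2.0, 0.0),
    "triazolam":   (343.2, 0.10, 0.62, 25.0, 1.1, 0.92, 0.55, 2.5, 0.0),
    "quinidine":   (324.4, 0.13, 0.92, 15.0, 2.7, 0.76, 0.90, 1.2, 3.0),
}

VICTIM_LIBRARY = tuple(_VICTIM_PARAMS)


def victim_profile(name: str) -> CompoundProfile:
    """Curated minimal-PBPK profile of a CYP3A4 probe substrate."""
    try:
        mw, fu, bp, cl, vss, fm, fg, ka, clr = _VICTIM_PARAMS[name]
    except KeyError:
        raise ValueError(f"no curated profile for victim {name!r}") from None
    return profile_from_targets(name, mw=mw, fu_p=fu, bp=bp, cl_iv_plasma=cl,
                                vss=vss, fm_cyp3a4=fm, f_g=fg, ka=ka,
                                cl_renal=clr)


def make_compound_profile(archetype: str, **overrides) -> CompoundProfile:
    """Build a named compound archetype, optionally overriding fields.

    * ``midazolam_like`` — high-extraction victim, fm_CYP3A4 ≈ 0.93, F_G ≈ 0.5.
    * ``high_fg_victim`` / ``low_fg_victim`` — victims bracketing gut extraction.
    * ``rifampicin_like`` — perpetrator with fixed (empirical, already
      autoinduced) clearance and no CYP3A4-mediated elimination, so no
      autoinduction arises; induction parameters are attached per scenario.
    * ``autoinducer`` — carbamazepine-like perpetrator whose elimination is
      largely CYP3A4-mediated, so multiple dosing lowers its own exposure.
    """
    if archetype == "midazolam_like":
        prof = victim_profile("midazolam")
        prof = replace(prof, name="midazolam_like")
    elif archetype == "high_fg_victim":
        prof = profile_from_targets("high_fg_victim", mw=350.0, fu_p=0.1, bp=0.8,
                                    cl_iv_plasma=12.0, vss=1.0, fm_cyp3a4=0.9,
                                    f_g=0.9, ka=1.5)
    elif archetype == "low_fg_victim":
        prof = profile_from_targets("low_fg_victim", mw=350.0, fu_p=0.05, bp=0.7,
                                    cl_iv_plasma=30.0, vss=1.0, fm_cyp3a4=0.9,
                                    f_g=0.3, ka=1.5)
    elif archetype == "rifampicin_like":
        # empirical steady-state oral clearance (fu_B * CLu_int = 14 L/h) as a
        # single non-CYP3A4 hepatic pathway: fixed CL, no autoinduction
        prof = CompoundProfile(
            name="rifampicin_like", mw=822.94, fu_p=0.15, bp=0.9, fu_gut=0.19,
            kp_liver=1.0, ka=1.0, fa=1.0, vss=0.7, cl_renal=0.0,
            elimination=(PathwayClearance("other", "liver", clu_int=84.0),),
            induction=SiteInduction(8.0, 0.32, 8.0, 0.32))
    elif archetype == "autoinducer":
        # carbamazepine-like: mostly CYP3A4-mediated elimination plus mRNA-
        # calibrated induction parameters (refined-reference scaling)
        prof = CompoundProfile(
            name="autoinducer", mw=236.3, fu_p=0.25, bp=1.0, fu_gut=0.9,
            kp_liver=1.5, ka=0.5, fa=1.0, vss=1.0, cl_renal=0.1,
            elimination=(
                PathwayClearance("CYP3A4", "liver", clu_int=10.0),
                PathwayClearance("other", "liver", clu_int=4.0),
            ),
            induction=SiteInduction(11.8, 26.5, 11.8, 26.5))
    else:
        raise ValueError(f"unknown archetype {archetype!r}")
    if overrides:
        prof = replace(prof, **overrides)
    return prof


# ---------------------------------------------------------------------------
# synthetic observed-study tables
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SyntheticStudySpec:
    n_studies: int = 6
    victims: tuple[str, ...] = ("midazolam_like", "high_fg_victim", "low_fg_victim")
    routes: tuple[str, ...] = ("oral", "iv_bolus")
    perp_dose_mg: float = 600.0
    perp_days: int = 7
    victim_dose_mg: float = 5.0
    stagger_h: float = 12.0
    n_subjects: int = 6
    truth: SiteInduction = SiteInduction(16.0, 0.32, 16.0, 0.32)
    obs_noise_cv: float = 0.0   # log-normal noise on each observed AUC
    seed: int = 0


def make_study_table(
    spec: SyntheticStudySpec,
    system: SystemParameters = SystemParameters(),
    options: SimOptions = SimOptions(),
) -> tuple[list[DDIStudyDesign], list, dict]:
    """Generate synthetic observed studies by running the simulator at truth.

    "Observed" control/induced AUCs are the reference-subject predictions
    under the truth induction parameters, perturbed by independent
    multiplicative log-normal observation noise (noise on AUCs, not ratios,
    mimicking crossover read-outs).  Returns (designs, observed records,
    ground truth) so recovery tests can compare against the known truth.
    """
    from .evaluate import ObservedStudy
    from .trial import run_study

    rng = np.random.default_rng(spec.seed)
    perp = make_compound_profile("rifampicin_like", induction=spec.truth)
    no_cv = CVConfig(cv_cyp3a4_h=0, cv_cyp3a4_g=0, cv_clu=0, cv_ka=0,
                     cv_vss=0, cv_qh=0, bw_cv=0)
    designs, observed = [], []
    truth_ratios = {}
    for k in range(spec.n_studies):
        victim_name = spec.victims[k % len(spec.victims)]
        route = spec.routes[k % len(spec.routes)]
        victim = make_compound_profile(victim_name)
        design = DDIStudyDesign(
            study_id=f"SYN{k + 1:02d}",
            perpetrator=(DoseRegimen(perp.name, spec.perp_dose_mg, "oral",
                                     24.0, spec.perp_days),),
            victim=DoseRegimen(victim.name, spec.victim_dose_mg, route),
            stagger_h=spec.stagger_h,
            n_subjects=spec.n_subjects, n_trials=1)
        run = run_study(design, victim, perp, system, cv=no_cv,
                        seed=spec.seed + k, options=options,
                        model_label="truth")
        true_ratio = run.pooled_ratio()
        auc_c = float(np.mean([p.auc_control for p in run.pairs])) * 1000.0  # ng/mL·h
        auc_i = auc_c / true_ratio
        auc_c_obs = auc_c * float(_lognormal_mult(rng, spec.obs_noise_cv))
        auc_i_obs = auc_i * float(_lognormal_mult(rng, spec.obs_noise_cv))
        observed.append(ObservedStudy(
            study_id=design.study_id, victim=victim_name, route=route,
            n=spec.n_subjects, auc_control=auc_c_obs, auc_induced=auc_i_obs,
            ratio_printed=auc_c_obs / auc_i_obs))
        designs.append(replace(design, observed=observed[-1]))
        truth_ratios[design.study_id] = true_ratio
    truth = {"induction": spec.truth, "ratios": truth_ratios}
    return designs, observed, truth
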