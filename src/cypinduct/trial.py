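"""Virtual DDI trials: population variability and paired study replication.

Each clinical study is replicated as ``n_trials`` virtual trials of
``n_subjects`` subjects matched to the published design (doses, routes,
stagger, duration, n).  Between-subject variability enters as independent
log-normal multipliers (median 1) on enzyme abundances, intrinsic
clearances, absorption rate and distribution volume, plus a truncated-normal
body weight; the published correlated-covariate machinery is deliberately
simplified away because the DDI endpoints are ratio-based.

Both study arms of a subject share all physiology (paired crossover design):
the control arm doses the victim alone, the induced arm doses the victim
``stagger`` hours after the start of the last scheduled perpetrator dose.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from typing import Any, Optional, Sequence

import numpy as np

from .pbpk import (
    CompoundProfile,
    DoseRegimen,
    SimOptions,
    SimulationResult,
    SystemParameters,
    baseline_metrics,
    simulate,
)

__all__ = [
    "DoseRegimen",
    "CVConfig",
    "DDIStudyDesign",
    "SubjectPhysiology",
    "SubjectPair",
    "StudyRun",
    "sample_population",
    "apply_subject",
    "run_study",
    "run_control_arm",
    "run_induced_arm",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CVConfig:
    """Coefficients of variation of the log-normal population multipliers."""

    cv_cyp3a4_h: float = 0.45
    cv_cyp3a4_g: float = 0.45
    cv_clu: float = 0.30
    cv_ka: float = 0.25
    cv_vss: float = 0.15
    cv_qh: float = 0.10
    bw_mean: float = 70.0
    bw_cv: float = 0.15

    def __post_init__(self) -> None:
        for name in ("cv_cyp3a4_h", "cv_cyp3a4_g", "cv_clu", "cv_ka",
                     "cv_vss", "cv_qh", "bw_cv"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class DDIStudyDesign:
    """One clinical DDI study replica: perpetrator schedule + victim dose."""

    study_id: str
    perpetrator: tuple[DoseRegimen, ...]
    victim: DoseRegimen
    stagger_h: float
    n_subjects: int
    n_trials: int = 10
    age_range: tuple[int, int] = (20, 50)
    proportion_female: float = 0.5
    stagger_ambiguous: bool = False
    observed: Optional[Any] = None  # ObservedStudy, attached by the fixture loader

    def __post_init__(self) -> None:
        object.__setattr__(self, "perpetrator", tuple(self.perpetrator))
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        if not (0 <= self.proportion_female <= 1):
            raise ValueError("proportion_female must be in [0, 1]")

    @property
    def victim_start_h(self) -> float:
        """Victim dose time: stagger hours after the last perpetrator dose start."""
        last = max(r.last_dose_time for r in self.perpetrator)
        return last + self.stagger_h


@dataclass(frozen=True)
class SubjectPhysiology:
    """One virtual subject: body weight and log-normal multipliers."""

    subject_id: int
    trial: int
    bw: float
    multipliers: dict[str, float]
    seed: int = 0

    def __post_init__(self) -> None:
        if self.bw <= 0:
            raise ValueError("body weight must be > 0")
        for k, v in self.multipliers.items():
            if v <= 0:
                raise ValueError(f"multiplier {k} must be > 0")


_MULT_KEYS = ("cyp3a4_h", "cyp3a4_g", "clu", "ka", "vss", "qh")


def _sigma(cv: float) -> float:
    return math.sqrt(math.log1p(cv * cv))


def sample_population(
    design: DDIStudyDesign,
    cv: CVConfig = CVConfig(),
    seed: int = 0,
) -> list[SubjectPhysiology]:
    """Draw ``n_trials × n_subjects`` virtual subjects, deterministic in seed.

    Multipliers are independent log-normals with median 1 whose geometric CV
    equals the configured CV; body weight is normal (truncated at ±3 SD).
    Age and sex are design labels only and do not alter physiology.
    """
    rng = np.random.default_rng(seed)
    cvs = {"cyp3a4_h": cv.cv_cyp3a4_h, "cyp3a4_g": cv.cv_cyp3a4_g,
           "clu": cv.cv_clu, "ka": cv.cv_ka, "vss": cv.cv_vss, "qh": cv.cv_qh}
    subjects = []
    sid = 0
    for trial in range(design.n_trials):
        for _ in range(design.n_subjects):
            mult = {}
            for key in _MULT_KEYS:
                s = _sigma(cvs[key])
                mult[key] = float(np.exp(rng.normal(0.0, s))) if s > 0 else 1.0
            sd = cv.bw_mean * cv.bw_cv
            z = rng.normal()
            z = min(max(z, -3.0), 3.0)
            bw = cv.bw_mean + sd * z
            subjects.append(SubjectPhysiology(
                subject_id=sid, trial=trial, bw=bw, multipliers=mult, seed=seed))
            sid += 1
    return subjects


def apply_subject(
    profile: CompoundProfile, subject: SubjectPhysiology
) -> CompoundProfile:
    """Return a per-subject copy of a compound profile.

    CYP3A4 pathways scale with the subject's liver/gut enzyme abundance
    multipliers; all other clearances (and renal) scale with the generic
    intrinsic-clearance multiplier; ka and Vss get their own multipliers.
    """
    m = subject.multipliers
    pathways = []
    for p in profile.elimination:
        if p.enzyme == "CYP3A4":
            scale = m["cyp3a4_h"] if p.site == "liver" else m["cyp3a4_g"]
        else:
            scale = m["clu"]
        if p.clu_int is not None:
            pathways.append(replace(p, clu_int=p.clu_int * scale))
        else:
            pathways.append(replace(p, vmax=p.vmax * scale))
    return replace(
        profile,
        elimination=tuple(pathways),
        cl_renal=profile.cl_renal * m["clu"],
        ka=profile.ka * m["ka"],
        vss=profile.vss * m["vss"],
    )


def _subject_system(system: SystemParameters, subject: SubjectPhysiology) -> SystemParameters:
    # portal flow stays a fixed fraction of hepatic blood flow
    m = subject.multipliers["qh"]
    return replace(system, q_h=system.q_h * m, q_pv=system.q_pv * m, bw=subject.bw)


@dataclass
class SubjectPair:
    subject: SubjectPhysiology
    auc_control: float
    auc_induced: float
    cmax_control: float
    cmax_induced: float

    @property
    def ratio_recip(self) -> float:
        """1/AUC ratio = AUC_control / AUC_induced (> 1 under induction)."""
        return self.auc_control / self.auc_induced

    @property
    def cmax_ratio_recip(self) -> float:
        return self.cmax_control / self.cmax_induced


@dataclass
class StudyRun:
    study_id: str
    model: str
    pairs: list[SubjectPair]

    def trial_geomeans(self) -> dict[int, float]:
        by_trial: dict[int, list[float]] = {}
        for p in self.pairs:
            by_trial.setdefault(p.subject.trial, []).append(p.ratio_recip)
        return {t: float(np.exp(np.mean(np.log(r)))) for t, r in sorted(by_trial.items())}

    def pooled_ratio(self) -> float:
        """Geometric mean of trial geometric means, equally weighted."""
        gm = list(self.trial_geomeans().values())
        return float(np.exp(np.mean(np.log(gm))))


def _victim_window(victim: CompoundProfile, regimen: DoseRegimen,
                   system: SystemParameters, n_half_lives: float = 5.0) -> float:
    t_half = baseline_metrics(victim, system)["t_half_h"]
    if not math.isfinite(t_half):
        t_half = 24.0
    span = regimen.interval_h * (regimen.n_doses - 1) if regimen.n_doses > 1 else 0.0
    return span + max(n_half_lives * t_half, 24.0)


def _auc_of(res: SimulationResult, study_id: str) -> float:
    if res.auc_0_inf is not None and res.auc_tail_ok:
        return res.auc_0_inf
    logger.warning("study %s: AUC_0_inf tail not identifiable; using AUC_0_t", study_id)
    return res.auc_0_t if res.auc_0_inf is None else res.auc_0_inf


def run_control_arm(
    design: DDIStudyDesign,
    victim_profile: CompoundProfile,
    system: SystemParameters,
    subjects: Sequence[SubjectPhysiology],
    options: SimOptions = SimOptions(),
) -> list[SimulationResult]:
    """Victim-alone simulations (model-independent) for every subject."""
    out = []
    for subj in subjects:
        v = apply_subject(victim_profile, subj)
        sys_s = _subject_system(system, subj)
        reg = replace(design.victim, compound=v.name, start_time_h=0.0)
        horizon = reg.last_dose_time + _victim_window(v, reg, sys_s)
        sim = simulate([v], [reg], sys_s, replace(options, horizon_h=horizon))
        out.append(sim[v.name])
    return out


def run_induced_arm(
    design: DDIStudyDesign,
    victim_profile: CompoundProfile,
    perp_profile: CompoundProfile,
    system: SystemParameters,
    subjects: Sequence[SubjectPhysiology],
    options: SimOptions = SimOptions(),
) -> list[SimulationResult]:
    """Perpetrator pretreatment + victim simulations for every subject.

    Runs in two stages: the pretreatment phase integrates only the
    perpetrator and enzyme states; the victim window then continues the full
    joint system from the carried-over state.
    """
    t_v = design.victim_start_h
    out = []
    for subj in subjects:
        v = apply_subject(victim_profile, subj)
        p = apply_subject(perp_profile, subj)
        sys_s = _subject_system(system, subj)
        victim_reg = replace(design.victim, compound=v.name, start_time_h=t_v)
        window = _victim_window(v, victim_reg, sys_s)
        horizon = victim_reg.last_dose_time + window
        if options.horizon_h is not None and options.horizon_h < horizon:
            raise ValueError(
                f"study {design.study_id}: victim sampling window is truncated "
                f"by the horizon ({options.horizon_h} < {horizon} h)")
        pre_regs = [replace(r, compound=p.name) for r in design.perpetrator]
        if t_v > 0:
            # pretreatment integrates only the perpetrator and enzyme pools
            stage1 = simulate([p], pre_regs, sys_s,
                              replace(options, horizon_h=max(t_v, 1e-6),
                                      track=(), points_per_segment=2))
            init_enz = stage1.final_enzymes
            init_amt = {p.name: stage1.final_amounts[p.name]}
        else:
            init_enz, init_amt = (1.0, 1.0), {}
        stage2 = simulate(
            [v, p], [victim_reg] + pre_regs, sys_s,
            replace(options, horizon_h=horizon, start_time_h=max(t_v, 0.0),
                    initial_enzymes=init_enz, initial_amounts=init_amt,
                    track=(v.name,)))
        out.append(stage2[v.name])
    return out


def run_study(
    design: DDIStudyDesign,
    victim_profile: CompoundProfile,
    perp_profile: CompoundProfile,
    system: SystemParameters = SystemParameters(),
    cv: CVConfig = CVConfig(),
    seed: int = 0,
    options: SimOptions = SimOptions(),
    subjects: Optional[Sequence[SubjectPhysiology]] = None,
    model_label: str = "",
) -> StudyRun:
    """Paired control/induced virtual replication of one clinical study."""
    if subjects is None:
        subjects = sample_population(design, cv, seed)
    control = run_control_arm(design, victim_profile, system, subjects, options)
    induced = run_induced_arm(design, victim_profile, perp_profile, system,
                              subjects, options)
    pairs = []
    for subj, rc, ri in zip(subjects, control, induced):
        pairs.append(SubjectPair(
            subject=subj,
            auc_control=_auc_of(rc, design.study_id),
            auc_induced=_auc_of(ri, design.study_id),
            cmax_control=rc.cmax, cmax_induced=ri.cmax))
    return StudyRun(study_id=design.study_id, model=model_label, pairs=pairs)
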