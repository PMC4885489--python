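"""DDI endpoint scoring: reciprocal AUC ratios, GMFE, RMSE, Guest limits.

Induction lowers victim exposure, so AUC_induced/AUC_control < 1; all
reporting uses the reciprocal ratio R = AUC_control/AUC_induced (> 1 under
induction).  Prediction accuracy over a study set is summarized as

    GMFE = 10 ** mean(|log10(predicted/observed)|)
    RMSE = sqrt(mean((predicted - observed)**2))

plus the fraction of predictions inside observed-ratio-dependent acceptance
limits, L = (delta + 2*(R - 1)) / R with interval [R/L, R*L] — a concordance
window narrower than the classic two-fold rule for small interactions.

``scenario_sweep`` replicates a study set under each rifampicin induction
scenario (models A–G) and tabulates accuracy per subgroup; the control arm
is shared across scenarios since it does not depend on the perpetrator model.
"""

from __future__ import annotations

import logging
import math
import zlib
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .calibration import reference_set
from .pbpk import CompoundProfile, SimOptions, SystemParameters
from .trial import CVConfig, DDIStudyDesign, StudyRun, SubjectPair, \
    run_control_arm, run_induced_arm, sample_population, _auc_of

__all__ = [
    "ObservedStudy",
    "DDIResult",
    "AccuracySummary",
    "reciprocal_ratio",
    "gmfe",
    "rmse",
    "acceptance_limits",
    "within_limits",
    "percent_within_limits",
    "meta_geomean",
    "summarize_accuracy",
    "pool_trials",
    "scenario_sweep",
    "sensitivity_sweep",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ObservedStudy:
    """Observed exposure of one clinical study, as printed in its report.

    ``ratio_printed`` is authoritative; ``ratio_source`` records whether it
    is the quotient of the printed AUC columns ("auc") or was derived
    differently in the source (e.g. from dose-corrected clearances in
    dose-escalated designs, "clearance") and therefore cannot be recomputed
    from the AUC columns.
    """

    study_id: str
    victim: str
    route: str
    n: int
    auc_control: float
    auc_induced: float
    ratio_printed: float
    ratio_source: str = "auc"
    auc_units: str = "ng/mL.h"

    def __post_init__(self) -> None:
        if self.auc_control <= 0 or self.auc_induced <= 0:
            raise ValueError("AUCs must be > 0")
        if self.ratio_printed <= 0:
            raise ValueError("ratio must be > 0")

    @property
    def ratio_recip(self) -> float:
        return self.ratio_printed

    def recomputed_ratio(self) -> float:
        return reciprocal_ratio(self.auc_control, self.auc_induced)


def reciprocal_ratio(auc_control: float, auc_induced: float) -> float:
    """1/AUC ratio = AUC_control / AUC_induced (> 1 under induction)."""
    if auc_control <= 0 or auc_induced <= 0:
        raise ValueError("AUCs must be > 0")
    return auc_control / auc_induced


def gmfe(pairs: Sequence[tuple[float, float]]) -> float:
    """Geometric mean fold error, 10**mean(|log10(pred/obs)|); 1 = perfect."""
    if not pairs:
        raise ValueError("empty pair list")
    logs = [abs(math.log10(p / o)) for p, o in _checked(pairs)]
    return 10.0 ** (sum(logs) / len(logs))


def rmse(pairs: Sequence[tuple[float, float]]) -> float:
    """Root-mean-square error of predicted vs observed ratios."""
    if not pairs:
        raise ValueError("empty pair list")
    return math.sqrt(sum((p - o) ** 2 for p, o in _checked(pairs)) / len(pairs))


def _checked(pairs):
    for p, o in pairs:
        if p <= 0 or o <= 0:
            raise ValueError("ratios must be > 0")
        yield p, o


def acceptance_limits(observed_ratio: float, delta: float = 1.25) -> tuple[float, float]:
    """Observed-ratio-dependent acceptance interval [R/L, R*L].

    L = (delta + 2*(R - 1)) / R, applied to reciprocal ratios R >= 1; ratios
    below 1 are transformed via their reciprocal first.  The interval
    collapses to a point at R = 1, delta = 1 and approaches the classic
    two-fold window for large R.
    """
    if delta < 1:
        raise ValueError("delta must be >= 1")
    r = observed_ratio
    if r <= 0:
        raise ValueError("observed ratio must be > 0")
    if r < 1:
        lo, hi = acceptance_limits(1.0 / r, delta)
        return 1.0 / hi, 1.0 / lo
    limit = (delta + 2.0 * (r - 1.0)) / r
    return r / limit, r * limit


def within_limits(predicted: float, observed: float, delta: float = 1.25) -> bool:
    lo, hi = acceptance_limits(observed, delta)
    return lo <= predicted <= hi


def percent_within_limits(pairs: Sequence[tuple[float, float]], delta: float = 1.25) -> float:
    pairs = list(pairs)
    if not pairs:
        raise ValueError("empty pair list")
    n_ok = sum(within_limits(p, o, delta) for p, o in pairs)
    return 100.0 * n_ok / len(pairs)


def meta_geomean(ratios: Sequence[float], weights: Optional[Sequence[float]] = None) -> float:
    """Unweighted (default) geometric mean of observed fold-induction ratios."""
    ratios = np.asarray(list(ratios), dtype=float)
    if ratios.size == 0:
        raise ValueError("empty ratio list")
    if np.any(ratios <= 0):
        raise ValueError("ratios must be > 0")
    if weights is None:
        return float(np.exp(np.mean(np.log(ratios))))
    w = np.asarray(list(weights), dtype=float)
    return float(np.exp(np.sum(w * np.log(ratios)) / np.sum(w)))


# ---------------------------------------------------------------------------
# result containers
# ---------------------------------------------------------------------------

@dataclass
class DDIResult:
    """Predicted interaction for one study under one perpetrator model."""

    study_id: str
    model: str
    trial_ratios: dict[int, float]
    pooled_ratio: float               # geometric mean of trial geometric means
    pooled_cmax_ratio: Optional[float]
    subject_ratios: list[float]
    observed: Optional[ObservedStudy] = None

    def __post_init__(self) -> None:
        vals = list(self.trial_ratios.values())
        if vals and not (min(vals) - 1e-9 <= self.pooled_ratio <= max(vals) + 1e-9):
            raise ValueError("pooled geometric mean must lie within the trial means")


def pool_trials(run: StudyRun, observed: Optional[ObservedStudy] = None) -> DDIResult:
    cmax_ratios = [p.cmax_ratio_recip for p in run.pairs]
    return DDIResult(
        study_id=run.study_id,
        model=run.model,
        trial_ratios=run.trial_geomeans(),
        pooled_ratio=run.pooled_ratio(),
        pooled_cmax_ratio=float(np.exp(np.mean(np.log(cmax_ratios)))) if cmax_ratios else None,
        subject_ratios=[p.ratio_recip for p in run.pairs],
        observed=observed,
    )


@dataclass(frozen=True)
class AccuracySummary:
    model: str
    subgroup: str
    gmfe: float
    rmse: float
    percent_within_limits: float
    n_studies: int

    def __post_init__(self) -> None:
        if self.gmfe < 1:
            raise ValueError("GMFE must be >= 1")
        if not (0 <= self.percent_within_limits <= 100):
            raise ValueError("percent_within_limits must be in [0, 100]")


_SUBGROUPS = {
    "iv_mdz": lambda o: o.victim == "midazolam" and o.route.startswith("iv"),
    "oral_mdz": lambda o: o.victim == "midazolam" and o.route == "oral",
    "all_iv": lambda o: o.route.startswith("iv"),
    "all_oral": lambda o: o.route == "oral",
    "all": lambda o: True,
}


def summarize_accuracy(
    results: Sequence[DDIResult], model: str, delta: float = 1.25,
) -> list[AccuracySummary]:
    """Per-subgroup GMFE/RMSE/%-within-limits for one model's predictions."""
    scored = [r for r in results if r.observed is not None]
    for r in results:
        if r.observed is None:
            logger.warning("study %s has no observed ratio; excluded from scoring",
                           r.study_id)
    out = []
    for name, keep in _SUBGROUPS.items():
        sel = [(r.pooled_ratio, r.observed.ratio_recip) for r in scored if keep(r.observed)]
        if not sel:
            continue
        out.append(AccuracySummary(
            model=model, subgroup=name,
            gmfe=gmfe(sel), rmse=rmse(sel),
            percent_within_limits=percent_within_limits(sel, delta),
            n_studies=len(sel)))
    return out


# ---------------------------------------------------------------------------
# scenario & sensitivity sweeps
# ---------------------------------------------------------------------------

def scenario_sweep(
    studies: Sequence[tuple[DDIStudyDesign, CompoundProfile]],
    perp_profile: CompoundProfile,
    models: Sequence[str] = ("model_A", "model_B", "model_C", "model_D",
                             "model_E", "model_F", "model_G"),
    seed: int = 0,
    system: SystemParameters = SystemParameters(),
    cv: CVConfig = CVConfig(),
    options: SimOptions = SimOptions(),
    delta: float = 1.25,
    n_subjects: Optional[int] = None,
    n_trials: Optional[int] = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Replicate a study set under each rifampicin induction scenario.

    ``studies`` pairs each design (with its observed record attached) with
    the victim's compound profile.  Returns (summary, per_study) tidy frames.
    The control arm and the virtual population are shared across models;
    ``n_subjects``/``n_trials`` override the designs for scaled-down runs.
    Reproducible given the seed.
    """
    per_model_results: dict[str, list[DDIResult]] = {m: [] for m in models}
    rows = []
    for design, victim_profile in studies:
        if n_subjects is not None or n_trials is not None:
            design = replace(design,
                             n_subjects=n_subjects or design.n_subjects,
                             n_trials=n_trials or design.n_trials)
        # per-study seed keyed on the study id, so the same subjects are drawn
        # regardless of which study subset is swept
        subj_seed = (seed * 131071 + zlib.crc32(design.study_id.encode())) % (2 ** 31)
        subjects = sample_population(design, cv, seed=subj_seed)
        control = run_control_arm(design, victim_profile, system, subjects, options)
        for model in models:
            perp = replace(perp_profile, induction=reference_set(model))
            induced = run_induced_arm(design, victim_profile, perp, system,
                                      subjects, options)
            pairs = [SubjectPair(subject=s,
                                 auc_control=_auc_of(rc, design.study_id),
                                 auc_induced=_auc_of(ri, design.study_id),
                                 cmax_control=rc.cmax, cmax_induced=ri.cmax)
                     for s, rc, ri in zip(subjects, control, induced)]
            run = StudyRun(study_id=design.study_id, model=model, pairs=pairs)
            res = pool_trials(run, observed=design.observed)
            per_model_results[model].append(res)
            obs = design.observed
            rows.append({
                "study_id": design.study_id, "model": model,
                "victim": obs.victim if obs else victim_profile.name,
                "route": design.victim.route,
                "predicted_ratio": res.pooled_ratio,
                "observed_ratio": obs.ratio_recip if obs else math.nan,
                "fold_error": (res.pooled_ratio / obs.ratio_recip) if obs else math.nan,
                "within_limits": within_limits(res.pooled_ratio, obs.ratio_recip, delta)
                if obs else None,
            })
    summary_rows = []
    for model, results in per_model_results.items():
        for s in summarize_accuracy(results, model, delta):
            summary_rows.append({
                "model": s.model, "subgroup": s.subgroup, "gmfe": s.gmfe,
                "rmse": s.rmse, "percent_within_limits": s.percent_within_limits,
                "n_studies": s.n_studies})
    return pd.DataFrame(summary_rows), pd.DataFrame(rows)


def sensitivity_sweep(
    parameter: str,
    values: Sequence[float],
    design: DDIStudyDesign,
    victim_profile: CompoundProfile,
    perp_profile: CompoundProfile,
    system: SystemParameters = SystemParameters(),
    cv: Optional[CVConfig] = None,
    seed: int = 0,
    options: SimOptions = SimOptions(),
) -> pd.DataFrame:
    """Predicted 1/AUC ratio of one study across values of a turnover or
    gut-binding parameter (kdeg_H, kdeg_G, or the perpetrator's fu_gut).

    By default the sweep runs on the reference subject (no variability) so
    that the parameter effect is not confounded with sampling noise.
    """
    from .trial import run_study  # local import to keep module load order simple

    if parameter not in ("kdeg_h", "kdeg_g", "fu_gut_in"):
        raise ValueError(f"unknown sweep parameter {parameter!r}")
    if any(v <= 0 for v in values):
        raise ValueError("sweep values must be > 0")
    cv = cv or CVConfig(cv_cyp3a4_h=0, cv_cyp3a4_g=0, cv_clu=0, cv_ka=0,
                        cv_vss=0, cv_qh=0, bw_cv=0)
    rows = []
    for v in values:
        sys_v, perp_v = system, perp_profile
        if parameter in ("kdeg_h", "kdeg_g"):
            sys_v = replace(system, **{parameter: v})
        else:
            if not (0 < v <= 1):
                raise ValueError("fu_gut must be in (0, 1]")
            perp_v = replace(perp_profile, fu_gut=v)
        run = run_study(design, victim_profile, perp_v, sys_v, cv=cv, seed=seed,
                        options=options, model_label=f"{parameter}={v}")
        rows.append({"parameter": parameter, "value": v,
                     "predicted_ratio": run.pooled_ratio()})
    return pd.DataFrame(rows)
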