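"""File formats and fixtures: induction CSVs, compound/study configs,
transcribed clinical study tables, and provenance-stamped result writers.

Tabular outputs are tidy CSV with ``#``-prefixed header comments carrying the
run seed and a configuration hash so stochastic runs can be reproduced.
Compound profiles and study designs are JSON or YAML (dialect by extension)
validated against the domain-type invariants with a strict key schema.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from importlib import resources
from pathlib import Path
from typing import Any, Optional, Sequence

import pandas as pd
import yaml

from .calibration import SiteInduction
from .evaluate import ObservedStudy
from .induction import DonorSummary, InductionDataset
from .pbpk import CompoundProfile, DoseRegimen, MBIParams, PathwayClearance
from .trial import DDIStudyDesign

__all__ = [
    "RunConfig",
    "read_induction_csv",
    "write_induction_csv",
    "write_donor_summary_csv",
    "read_compound_profile",
    "write_compound_profile",
    "read_study_design",
    "load_rifampicin_studies",
    "load_other_inducer_studies",
    "parse_schedule",
    "write_results_csv",
    "read_results_csv",
]

logger = logging.getLogger(__name__)

_INDUCTION_COLUMNS = ("inducer", "donor", "endpoint", "conc_uM", "fold")


@dataclasses.dataclass(frozen=True)
class RunConfig:
    """Paths, model choices and seeds of one pipeline run."""

    output_dir: str = "."
    induction_data: Optional[str] = None
    compound_profiles: tuple[str, ...] = ()
    study_designs: Optional[str] = None
    model: str = "model_C"
    calibration_convention: str = "emax_scaling"
    seed: int = 0
    rtol: float = 1e-6
    atol: float = 1e-9
    cv_cyp3a4: float = 0.45
    cv_clu: float = 0.30
    cv_ka: float = 0.25

    def __post_init__(self) -> None:
        if not isinstance(self.seed, int):
            raise ValueError("seed must be an integer")
        if self.rtol <= 0 or self.atol <= 0:
            raise ValueError("solver tolerances must be > 0")

    def digest(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


# ---------------------------------------------------------------------------
# induction data
# ---------------------------------------------------------------------------

def read_induction_csv(path: str | Path) -> list[InductionDataset]:
    """Read hepatocyte induction data grouped by (inducer, donor, endpoint).

    Malformed rows (non-positive concentration or fold, missing values) are
    rejected individually with their line numbers; the remainder loads.
    """
    df = pd.read_csv(path, comment="#")
    missing = [c for c in _INDUCTION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing required columns: {missing}")
    if df.empty:
        logger.warning("induction file %s contains no data rows", path)
        return []
    bad = df["conc_uM"].isna() | df["fold"].isna() | (df["conc_uM"] <= 0) | (df["fold"] <= 0)
    for idx in df.index[bad]:
        logger.warning("%s line %d: rejected malformed row", path, idx + 2)
    df = df[~bad]
    datasets = []
    for (inducer, donor, endpoint), grp in df.groupby(
            ["inducer", "donor", "endpoint"], sort=True):
        datasets.append(InductionDataset(
            inducer=str(inducer), donor_id=str(donor), endpoint=str(endpoint),
            concentrations=grp["conc_uM"].to_numpy(float),
            fold_response=grp["fold"].to_numpy(float)))
    return datasets


def write_induction_csv(datasets: Sequence[InductionDataset], path: str | Path) -> None:
    rows = []
    for ds in datasets:
        for c, f in zip(ds.concentrations, ds.fold_response):
            rows.append({"inducer": ds.inducer, "donor": ds.donor_id,
                         "endpoint": ds.endpoint, "conc_uM": c, "fold": f})
    pd.DataFrame(rows, columns=list(_INDUCTION_COLUMNS)).to_csv(path, index=False)


def write_donor_summary_csv(summaries: Sequence[DonorSummary], path: str | Path) -> None:
    """Across-donor parameter summary in the shape of a mean/SD table."""
    rows = [{
        "inducer": s.inducer, "endpoint": s.endpoint,
        "mean_Ind_max": s.mean_ind_max, "sd_Ind_max": s.sd_ind_max,
        "mean_IndC_50": s.mean_indc50, "sd_IndC_50": s.sd_indc50,
        "n_donors": s.n_donors,
    } for s in summaries]
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.12g")


# ---------------------------------------------------------------------------
# compound profiles and study designs (JSON/YAML, strict schema)
# ---------------------------------------------------------------------------

def _load_structured(path: Path) -> dict:
    text = path.read_text()
    if path.suffix.lower() in (".yaml", ".yml"):
        return yaml.safe_load(text)
    return json.loads(text)


def _dump_structured(data: dict, path: Path) -> None:
    if path.suffix.lower() in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(data, sort_keys=False))
    else:
        path.write_text(json.dumps(data, indent=2))


def _strict(d: dict, allowed: set[str], context: str) -> None:
    unknown = set(d) - allowed
    if unknown:
        raise ValueError(f"{context}: unknown keys {sorted(unknown)}")


_PROFILE_KEYS = {
    "name", "mw", "fu_p", "bp", "fu_gut", "kp_liver", "ka", "fa", "vss",
    "cl_renal", "elimination", "inhibition", "mbi", "induction",
}
_PATHWAY_KEYS = {"enzyme", "site", "clu_int", "vmax", "km_u"}
_INDUCTION_KEYS = {"ind_max_liver", "indc50_liver", "ind_max_gut", "indc50_gut"}


def profile_to_dict(profile: CompoundProfile) -> dict:
    d: dict[str, Any] = {
        "name": profile.name, "mw": profile.mw, "fu_p": profile.fu_p,
        "bp": profile.bp, "fu_gut": profile.fu_gut, "kp_liver": profile.kp_liver,
        "ka": profile.ka, "fa": profile.fa, "vss": profile.vss,
        "cl_renal": profile.cl_renal,
        "elimination": [
            {k: v for k, v in dataclasses.asdict(p).items() if v is not None}
            for p in profile.elimination],
    }
    if profile.inhibition:
        d["inhibition"] = dict(profile.inhibition)
    if profile.mbi is not None:
        d["mbi"] = dataclasses.asdict(profile.mbi)
    if profile.induction is not None:
        d["induction"] = dataclasses.asdict(profile.induction)
    return d


def profile_from_dict(d: dict) -> CompoundProfile:
    _strict(d, _PROFILE_KEYS, f"profile {d.get('name', '?')!r}")
    pathways = []
    for p in d.get("elimination", []):
        _strict(p, _PATHWAY_KEYS, "elimination pathway")
        pathways.append(PathwayClearance(**p))
    mbi = MBIParams(**d["mbi"]) if "mbi" in d else None
    induction = None
    if "induction" in d:
        _strict(d["induction"], _INDUCTION_KEYS, "induction")
        induction = SiteInduction(**d["induction"])
    scalar = {k: d[k] for k in d
              if k not in ("elimination", "inhibition", "mbi", "induction")}
    return CompoundProfile(elimination=tuple(pathways),
                           inhibition=d.get("inhibition", {}),
                           mbi=mbi, induction=induction, **scalar)


def read_compound_profile(path: str | Path) -> CompoundProfile:
    return profile_from_dict(_load_structured(Path(path)))


def write_compound_profile(profile: CompoundProfile, path: str | Path) -> None:
    _dump_structured(profile_to_dict(profile), Path(path))


_REGIMEN_KEYS = {"compound", "dose", "route", "interval_h", "n_doses",
                 "start_time_h", "per_kg", "infusion_duration_h"}
_DESIGN_KEYS = {"study_id", "perpetrator", "victim", "stagger_h", "n_subjects",
                "n_trials", "age_range", "proportion_female", "stagger_ambiguous"}


def _regimen_from_dict(d: dict) -> DoseRegimen:
    _strict(d, _REGIMEN_KEYS, "dose regimen")
    return DoseRegimen(**d)


def read_study_design(path: str | Path) -> DDIStudyDesign:
    d = _load_structured(Path(path))
    _strict(d, _DESIGN_KEYS, f"study {d.get('study_id', '?')!r}")
    perp = tuple(_regimen_from_dict(r) for r in d["perpetrator"])
    victim = _regimen_from_dict(d["victim"])
    rest = {k: d[k] for k in d if k not in ("perpetrator", "victim")}
    if "age_range" in rest:
        rest["age_range"] = tuple(rest["age_range"])
    return DDIStudyDesign(perpetrator=perp, victim=victim, **rest)


# ---------------------------------------------------------------------------
# transcribed clinical study fixtures
# ---------------------------------------------------------------------------

def parse_schedule(schedule: str, compound: str) -> tuple[DoseRegimen, ...]:
    """Parse a compact schedule like ``600x5q24`` or ``200x4q12+400x28q12``.

    Each phase is dose_mg x n_doses q interval_h; consecutive phases start at
    the next dose slot after the previous phase ends.
    """
    regimens = []
    t0 = 0.0
    for phase in schedule.split("+"):
        dose_s, rest = phase.split("x")
        n_s, q_s = rest.split("q")
        dose, n, q = float(dose_s), int(n_s), float(q_s)
        regimens.append(DoseRegimen(compound=compound, dose=dose, route="oral",
                                    interval_h=q, n_doses=n, start_time_h=t0))
        t0 += n * q
    return tuple(regimens)


def _load_study_table(resource: str) -> list[DDIStudyDesign]:
    with resources.files("cypinduct.data").joinpath(resource).open() as fh:
        df = pd.read_csv(fh)
    designs = []
    for _, row in df.iterrows():
        observed = ObservedStudy(
            study_id=row["study_id"], victim=row["victim"],
            route=row["victim_route"], n=int(row["n"]),
            auc_control=float(row["auc_control"]),
            auc_induced=float(row["auc_induced"]),
            ratio_printed=float(row["ratio_printed"]),
            ratio_source=row["ratio_source"], auc_units=row["auc_units"])
        victim_reg = DoseRegimen(
            compound=row["victim"], dose=float(row["victim_dose"]),
            route=row["victim_route"], per_kg=bool(row["dose_per_kg"]))
        designs.append(DDIStudyDesign(
            study_id=row["study_id"],
            perpetrator=parse_schedule(row["perp_schedule"], row["inducer"]),
            victim=victim_reg,
            stagger_h=float(row["stagger_h"]),
            stagger_ambiguous=bool(row["stagger_ambiguous"]),
            n_subjects=int(row["n"]),
            observed=observed))
    return designs


def load_rifampicin_studies() -> list[DDIStudyDesign]:
    """The 29 transcribed rifampicin DDI studies (10 i.v., 19 oral victims)."""
    return _load_study_table("rifampicin_studies.csv")


def load_other_inducer_studies() -> list[DDIStudyDesign]:
    """The 6 carbamazepine/phenytoin/phenobarbital DDI studies."""
    return _load_study_table("other_inducer_studies.csv")


# ---------------------------------------------------------------------------
# provenance-stamped results
# ---------------------------------------------------------------------------

def write_results_csv(df: pd.DataFrame, path: str | Path,
                      seed: Optional[int] = None,
                      config: Optional[RunConfig] = None,
                      extra: Optional[dict] = None) -> None:
    path = Path(path)
    lines = ["# cypinduct results"]
    if config is not None:
        lines.append(f"# config_hash: {config.digest()}")
    if seed is not None:
        lines.append(f"# seed: {seed}")
    for k, v in (extra or {}).items():
        lines.append(f"# {k}: {v}")
    with path.open("w") as fh:
        fh.write("\n".join(lines) + "\n")
        df.to_csv(fh, index=False, float_format="%.12g")


def read_results_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")
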