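"""Concentration–response fitting of in vitro CYP3A4 induction data.

Cryopreserved-hepatocyte induction assays report fold change over vehicle
control (mRNA or enzyme activity) across a concentration grid of an inducer.
Each donor's curve is fitted with a sigmoidal model

    fold(C) = baseline + (Ind_max - baseline) * C**hill / (IndC_50**hill + C**hill)

where ``Ind_max`` is the maximal fold induction (the curve top, equal to
E_max + 1, uncorrected for baseline) and ``IndC_50`` the concentration giving
half-maximal fold induction.  The three-parameter model fixes ``hill = 1``;
the four-parameter model frees it.  Donor-level fits are aggregated into
arithmetic mean and sample standard deviation per inducer/endpoint.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Literal, Optional, Sequence

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "InductionDataset",
    "InductionFit",
    "DonorSummary",
    "fit_sigmoid",
    "summarize_donors",
    "predict_fold",
]

logger = logging.getLogger(__name__)

Endpoint = Literal["mRNA", "activity"]

#: bounds for the fitted vehicle-control baseline (fold units); fits whose
#: baseline leaves this window are rejected upstream by the dataset QC.
BASELINE_BOUNDS = (0.5, 2.0)

#: relative standard error on IndC_50 above which a fit is flagged
#: ill-conditioned (flat curves leave the midpoint unidentified).
ILL_CONDITIONED_RSE = 10.0


@dataclass(frozen=True)
class InductionDataset:
    """Fold-over-vehicle induction measurements for one donor and inducer."""

    inducer: str
    donor_id: str
    endpoint: Endpoint
    concentrations: np.ndarray  # µM
    fold_response: np.ndarray   # dimensionless, paired with concentrations
    replicate_id: Optional[int] = None

    def __post_init__(self) -> None:
        conc = np.asarray(self.concentrations, dtype=float)
        fold = np.asarray(self.fold_response, dtype=float)
        object.__setattr__(self, "concentrations", conc)
        object.__setattr__(self, "fold_response", fold)
        if self.endpoint not in ("mRNA", "activity"):
            raise ValueError(f"unknown endpoint {self.endpoint!r}")
        if conc.shape != fold.shape or conc.ndim != 1:
            raise ValueError("concentrations and fold_response must be 1-D and paired")
        if np.any(conc <= 0):
            raise ValueError("concentrations must be strictly positive")
        if np.any(fold <= 0):
            raise ValueError("fold_response must be strictly positive")
        # uniqueness applies within a replicate; replicate wells may repeat a level
        if self.replicate_id is None and len(np.unique(conc)) != len(conc):
            raise ValueError("concentrations must be unique within a replicate")

    @property
    def n_levels(self) -> int:
        return len(np.unique(self.concentrations))


@dataclass(frozen=True)
class InductionFit:
    """Fitted sigmoidal induction parameters for one donor curve."""

    ind_max: float          # maximal fold induction (= E_max + 1)
    indc50: float           # µM at half-maximal fold induction
    hill: float
    baseline: float         # fitted fold at zero concentration
    se_ind_max: float
    se_indc50: float
    rss: float
    n_points: int
    converged: bool = True
    ill_conditioned: bool = False
    extrapolated: bool = False
    model: str = "three_param"
    inducer: str = ""
    donor_id: str = ""
    endpoint: str = ""

    def __post_init__(self) -> None:
        if self.converged:
            if self.ind_max < 1.0 - 1e-9:
                raise ValueError("Ind_max must be >= 1")
            if self.indc50 <= 0:
                raise ValueError("IndC_50 must be > 0")
            if self.hill <= 0:
                raise ValueError("Hill exponent must be > 0")


@dataclass(frozen=True)
class DonorSummary:
    """Across-donor mean and SD of induction parameters."""

    inducer: str
    endpoint: str
    mean_ind_max: float
    sd_ind_max: Optional[float]
    mean_indc50: float
    sd_indc50: Optional[float]
    n_donors: int

    def __post_init__(self) -> None:
        if self.n_donors < 1:
            raise ValueError("n_donors must be >= 1")
        if self.n_donors == 1 and (self.sd_ind_max is not None or self.sd_indc50 is not None):
            raise ValueError("sd fields must be absent for a single donor")


def _sigmoid(conc, baseline, ind_max, indc50, hill):
    c = np.power(conc, hill)
    return baseline + (ind_max - baseline) * c / (np.power(indc50, hill) + c)


def predict_fold(fit: InductionFit, conc: float) -> float:
    """Evaluate the fitted fold-induction curve at a concentration (µM).

    Returns the baseline at ``conc == 0``; monotone non-decreasing in ``conc``
    for inducers (``ind_max >= baseline``).
    """
    conc = float(conc)
    if conc < 0:
        raise ValueError("concentration must be >= 0")
    if conc == 0.0:
        return fit.baseline
    return float(_sigmoid(conc, fit.baseline, fit.ind_max, fit.indc50, fit.hill))


def _failed_fit(data: InductionDataset, model: str) -> InductionFit:
    return InductionFit(
        ind_max=math.nan, indc50=math.nan, hill=math.nan, baseline=math.nan,
        se_ind_max=math.nan, se_indc50=math.nan, rss=math.nan,
        n_points=len(data.concentrations), converged=False, model=model,
        inducer=data.inducer, donor_id=data.donor_id, endpoint=data.endpoint,
    )


def fit_sigmoid(
    data: InductionDataset,
    model: Literal["three_param", "four_param"] = "three_param",
) -> InductionFit:
    """Least-squares sigmoidal fit of one donor induction curve.

    ``three_param`` fixes the Hill exponent at 1 (baseline, top and midpoint
    free); ``four_param`` also frees the Hill exponent.  Fitting is done on
    the linear concentration scale, unweighted, multi-started over a
    log-spaced ``IndC_50`` grid for robustness on 7-point designs.

    Non-convergence returns a flagged failure result rather than raising;
    fewer distinct concentrations than free parameters is a precondition
    error.
    """
    if model not in ("three_param", "four_param"):
        raise ValueError(f"unknown model {model!r}")
    n_free = 3 if model == "three_param" else 4
    if data.n_levels < 4:
        raise ValueError("at least 4 distinct concentrations are required for fitting")
    if data.n_levels < n_free:
        raise ValueError("fewer concentration levels than free parameters")

    conc = data.concentrations
    fold = data.fold_response
    top0 = max(float(np.max(fold)), 1.0 + 1e-6)
    gm_conc = float(np.exp(np.mean(np.log(conc))))

    lo, hi = BASELINE_BOUNDS
    c_lo, c_hi = float(np.min(conc)), float(np.max(conc))
    if model == "three_param":
        def f(c, baseline, ind_max, indc50):
            return _sigmoid(c, baseline, ind_max, indc50, 1.0)
        bounds = ([lo, 1.0, c_lo * 1e-4], [hi, 1e4, c_hi * 1e4])
        starts = [(1.0, top0, x) for x in _logspace_starts(gm_conc, c_lo, c_hi)]
    else:
        def f(c, baseline, ind_max, indc50, hill):
            return _sigmoid(c, baseline, ind_max, indc50, hill)
        bounds = ([lo, 1.0, c_lo * 1e-4, 0.1], [hi, 1e4, c_hi * 1e4, 10.0])
        starts = [(1.0, top0, x, 1.0) for x in _logspace_starts(gm_conc, c_lo, c_hi)]

    best = None
    for p0 in starts:
        try:
            popt, pcov = curve_fit(
                f, conc, fold, p0=p0, bounds=bounds, maxfev=20000, method="trf"
            )
        except (RuntimeError, ValueError):
            continue
        rss = float(np.sum((f(conc, *popt) - fold) ** 2))
        if best is None or rss < best[2] - 1e-12:
            best = (popt, pcov, rss)
    if best is None:
        logger.warning("sigmoid fit failed to converge for %s/%s", data.inducer, data.donor_id)
        return _failed_fit(data, model)

    popt, pcov, rss = best
    se = np.sqrt(np.clip(np.diag(pcov), 0, np.inf))
    baseline, ind_max, indc50 = popt[0], popt[1], popt[2]
    hill = popt[3] if model == "four_param" else 1.0
    se_ind_max, se_indc50 = float(se[1]), float(se[2])
    rse_c50 = se_indc50 / indc50 if indc50 > 0 else math.inf
    ill = (not math.isfinite(rse_c50)) or rse_c50 > ILL_CONDITIONED_RSE \
        or (ind_max - baseline) < 0.05
    extrapolated = indc50 > c_hi
    if extrapolated:
        logger.info(
            "IndC_50 %.3g above highest tested concentration %.3g for %s/%s",
            indc50, c_hi, data.inducer, data.donor_id,
        )
    return InductionFit(
        ind_max=float(max(ind_max, 1.0)), indc50=float(indc50), hill=float(hill),
        baseline=float(baseline), se_ind_max=se_ind_max, se_indc50=se_indc50,
        rss=rss, n_points=len(conc), converged=True, ill_conditioned=bool(ill),
        extrapolated=bool(extrapolated), model=model,
        inducer=data.inducer, donor_id=data.donor_id, endpoint=data.endpoint,
    )


def _logspace_starts(gm: float, lo: float, hi: float) -> list[float]:
    # geometric mean of the tested grid first, then a log-spaced sweep
    grid = np.geomspace(lo, hi, 5)
    return [gm] + [float(g) for g in grid]


def summarize_donors(fits: Sequence[InductionFit]) -> DonorSummary:
    """Arithmetic mean and (n-1) SD of Ind_max and IndC_50 across donors.

    Failed fits are excluded with a logged warning; all retained fits must
    share inducer and endpoint.
    """
    fits = list(fits)
    if not fits:
        raise ValueError("empty fit list")
    kept = [f for f in fits if f.converged]
    for f in fits:
        if not f.converged:
            logger.warning("excluding non-converged fit for donor %s", f.donor_id)
    if not kept:
        raise ValueError("no converged fits to summarize")
    endpoints = {f.endpoint for f in kept}
    inducers = {f.inducer for f in kept}
    if len(endpoints) > 1:
        raise ValueError(f"mixed endpoints in donor summary: {sorted(endpoints)}")
    if len(inducers) > 1:
        raise ValueError(f"mixed inducers in donor summary: {sorted(inducers)}")
    im = np.array([f.ind_max for f in kept])
    c50 = np.array([f.indc50 for f in kept])
    n = len(kept)
    return DonorSummary(
        inducer=kept[0].inducer,
        endpoint=kept[0].endpoint,
        mean_ind_max=float(np.mean(im)),
        sd_ind_max=float(np.std(im, ddof=1)) if n > 1 else None,
        mean_indc50=float(np.mean(c50)),
        sd_indc50=float(np.std(c50, ddof=1)) if n > 1 else None,
        n_donors=n,
    )
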