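# Methods

## Scope and model structure

`cypinduct` predicts CYP3A4-induction drug–drug interactions with a dynamic
(time-varying enzyme) mechanistic model. A minimal PBPK structure is used for
every compound: gut lumen, enterocyte, portal vein, liver, and one lumped
systemic compartment. Dosing enters the lumen (oral, first-order absorption
`ka`, fraction absorbed `Fa`) or the systemic pool (i.v. bolus/infusion).

Two structural simplifications keep population-scale virtual trials cheap
without changing the steady-state physics:

* **Quasi-steady enterocyte and portal pools.** Their turnover times
  (Q/V ≈ 70–100 h⁻¹) are two orders of magnitude faster than absorption,
  distribution or enzyme turnover, so both are solved algebraically. The
  gut-extraction and well-stirred closed forms then hold exactly:
  `E_G = fu_gut·CLu_G/(Q_gut + fu_gut·CLu_G)`,
  `CL_H,blood = Q_h·fu_B·CLu_H/(Q_h + fu_B·CLu_H)`.
* **One-way gut wall for mass balance.** The gut wall extracts only drug in
  oral transit; systemic drug is not cleared by the gut. This keeps
  `AUC_iv = Dose/CL` exact and isolates F_G as a first-pass quantity. The
  enterocyte concentration that *drives* gut-wall induction, however,
  includes the villous blood supply
  (`C_ent = (ka·Fa·A_lumen + Q_gut·C_blood)/(Q_gut + fu_gut·CLu_G)`), so a
  systemically available perpetrator keeps stimulating gut CYP3A4 between
  absorption pulses — without this, gut induction would switch off between
  doses, which contradicts observed oral interaction magnitudes.

## Enzyme turnover

Active CYP3A4 amounts in liver and gut are dimensionless (baseline 1) and
multiply every CYP3A4-mediated pathway clearance:

    dEnz/dt = k_deg·Enz_0·[1 + (Ind_max − 1)·I_u/(IndC_50 + I_u)]
              − k_deg·Enz − Enz·k_inact·I_u/(K_I + I_u)

with zero-order synthesis stimulated by induction, first-order degradation,
and an optional mechanism-based inactivation loss. Driving concentrations
are unbound: the liver equation uses unbound liver tissue concentration
(`fu_p·C_liver/Kp`, numerically the unbound emergent venous plasma level);
the gut equation uses the unbound enterocyte concentration (`fu_gut·C_ent`),
with the unbound portal-vein level available as an alternative driver
(`gut_driver="portal"`). Interaction constants (IndC_50, Ki_u, K_I) are in
µM and converted from mg/L by molecular weight at each step.

Avoiding absolute enzyme abundances is deliberate: all DDI endpoints are
ratios, and relative amounts are the only identifiable scale.

Defaults: `k_deg,H = 0.0193 h⁻¹` (hepatic CYP3A4 half-life ≈ 36 h),
`k_deg,G = 0.03 h⁻¹` (≈ 23 h), both configurable; `sensitivity_sweep`
exposes them and the perpetrator's fu_gut. For the linear turnover ODE the
steady-state fold is `1 + (Ind_max − 1)·I/(IndC_50 + I)` (independent of
k_deg) and the relaxation time constant is `1/k_deg` — both are tested
against closed forms.

## Clearances and interaction arithmetic

Each pathway contributes `CLu_int` (L/h whole organ, unbound) or
`Vmax/(Km_u·(1 + I_u/Ki_u) + S_u)` (liver only), scaled by the enzyme state
for CYP3A4 pathways and divided by the competitive-inhibition term
`1 + I_u/Ki_u` (1 when no Ki is given). Non-CYP3A4 pathways scale with
factor 1. Because every CYP3A4 pathway of every compound shares the same
enzyme states, autoinduction of a CYP3A4-cleared perpetrator emerges without
extra machinery.

AUC, C_max tail, fm_CYP3A4, F_G and F_H are computed from auxiliary
flux-integral ODE states (hepatic CYP3A4 flux, total hepatic flux, renal
flux, gut-wall metabolism and escape fluxes, liver inflow), so they carry
solver accuracy rather than output-grid accuracy. `AUC_0→∞` adds an analytic
terminal tail `C(T)/λ_z` with `λ_z = CL/(V_sys + Kp·V_liver)` at the final
enzyme state; the result is flagged when the tail exceeds 20 % of the total.
`extract_metrics` provides the independent trapezoid + log-linear-tail route.

## System parameters and units

70-kg reference adult: `Q_h = 90` L/h blood, `Q_pv = 70` L/h,
`Q_gut = 18` L/h (villous flow of the gut-extraction stage),
`V_liver = 1.7` L; systemic volume per compound is `Vss·BW`. Internal state
is mg and mg/L; reported AUCs are mg/L·h (multiply by 1000 for ng/mL·h).

## Calibration conventions

The default convention scales the baseline-corrected effect
(`emax_scaling`): since Ind_max is defined as E_max + 1, scaling E_max keeps
a no-effect compound (Ind_max = 1) at no effect. `indmax_scaling` (direct
fold ratio) is retained as an option and floored at 1, because a weak
inducer calibrated against a strong calibrator can otherwise map below the
no-induction bound. Self-calibration of the calibrator returns the in vivo
reference exactly under both conventions. The rifampicin scenario library
(models A–G) covers the base reference (8, 0.32 µM), the gut-only and
both-site refinements (16; 12; 20), and the uncalibrated activity/mRNA donor
means (22.7, 0.30; 29.9, 0.71).

## Virtual trials

Each clinical study is replicated as `n_trials × n_subjects` virtual
subjects matched to the published design (dose, route, schedule, stagger,
n). The victim is dosed `stagger` hours after the start of the last
scheduled perpetrator dose (negative stagger = victim first; ambiguous
staggers in the transcribed tables are taken at face value and flagged).
Between-subject variability is independent log-normal with median 1:
CV 45 % on hepatic and gut CYP3A4 abundance, 30 % on non-CYP3A4 intrinsic
and renal clearances, 25 % on ka, 15 % on Vss, 10 % on hepatic flow (portal
flow co-varies), body weight normal 70 kg CV 15 % truncated at ±3 SD. The
correlated-covariate population machinery of full simulators is deliberately
not reproduced: the endpoints are paired within-subject ratios, which are
insensitive to covariance structure at this level. Age and sex are design
labels only — a documented limitation.

Both arms of a subject share all physiology (crossover design). The induced
arm runs in two stages — perpetrator + enzymes alone through pretreatment,
then the joint system through the victim window — which is exact (the victim
does not influence the perpetrator here) and several-fold faster. Pooling is
the geometric mean of trial geometric means, equally weighted; the observed
meta-analysis geometric means are likewise unweighted (an n-weighted option
exists).

## Scoring

Reciprocal ratios `R = AUC_control/AUC_induced` (> 1 under induction);
`GMFE = 10^mean(|log10(pred/obs)|)`; `RMSE = sqrt(mean((pred − obs)²))`;
concordance limits `L = (δ + 2(R − 1))/R`, interval `[R/L, R·L]`, applied to
R ≥ 1 (reciprocal-transformed otherwise), with δ = 1.25 by default
(variability-adjusted form; δ = 1 available). The interval is never wider
than the classic two-fold window.

Two of the 35 transcribed studies report dose-escalated designs whose
printed ratios derive from dose-corrected clearances, not the printed AUC
columns; they carry `ratio_source="clearance"` and are excluded from
AUC-quotient round-trip checks. Two further rows in the
carbamazepine/phenytoin/phenobarbital table disagree with their AUC quotient
beyond printed rounding; the printed ratio is stored as authoritative
everywhere.

## Compound archetypes and the synthetic generator

The victim library holds curated minimal-PBPK profiles of the eight probe
substrates, built by back-calculating pathway clearances from literature
i.v. clearance, fm_CYP3A4 and F_G targets through the same closed forms the
simulator uses (e.g. midazolam: CL 27 L/h plasma, fm ≈ 0.93, F_G ≈ 0.5).
The rifampicin-like perpetrator uses an empirical fixed clearance
(fu_B·CLu_int = 14 L/h, i.e. oral CL/F ≈ 14 L/h, Cavg ≈ 1.8 mg/L at 600 mg
daily) representing the autoinduced steady state — its own elimination is
deliberately non-CYP3A4, so no autoinduction is simulated for it, matching
how empirical rifampicin models behave. The carbamazepine-like archetype is
the converse: largely CYP3A4-cleared plus its own induction parameters, so
multiple dosing lowers its troughs (autoinduction signature).

The induction-assay generator draws donor truths log-normally (on
Ind_max − 1, keeping Ind_max ≥ 1 by construction) with mean-1 multipliers so
arithmetic donor means converge to the configured truth; defaults mimic the
observed four-donor rifampicin-activity spread (CV ≈ 0.34 on Ind_max, 0.33
on IndC_50) with 15 % multiplicative residual noise on the standard assay
grids. The observed-study generator runs the simulator at truth parameters
and perturbs control and induced AUCs independently (noise on AUCs, not
ratios, mimicking crossover read-outs). What passing tests show: the
pipeline recovers its own generating process (closure, GMFE → 1 as noise
→ 0) and reproduces printed clinical summaries; they do not certify the
curated archetypes against unseen clinical data beyond the transcribed AUC
tables.

## Numerical choices

LSODA with rtol 1e-6/atol 1e-9 by default; population sweeps use rtol
1e-4/atol 1e-7 (predicted ratios agree to < 0.01 % with tighter settings, at
roughly a fifth of the cost). Dose events re-initialize the state at exact
times; infusions are piecewise-constant rates. Tiny negative interpolation
values are clipped at zero; a negative state beyond 1e-6 mg aborts with
diagnostics. Sigmoid fits run on the linear concentration scale, unweighted,
multi-started over a log-spaced IndC_50 grid (geometric grid mean first,
then a 5-point sweep) with baseline bounded to [0.5, 2]; flat curves are
flagged ill-conditioned (relative SE of IndC_50 > 10 or curve span < 0.05),
and fits with IndC_50 above the tested range are flagged extrapolated.
Replicate wells, when present, are fitted simultaneously rather than
averaged first.

The acceptance script scales the virtual-trial sweep to 5 subjects × 2
trials per study (the package's reporting default for quick reproduction);
the test suite runs the directional model-comparison checks at 10 × 10.

## Known limitations

* No full-body PBPK, multi-segment gut, transporters, permeability- or
  solubility-limited absorption; CYP3A5 and UGT induction are out of scope.
* The rifampicin exposure model is a fixed-clearance approximation of the
  autoinduced steady state; first doses are consequently underexposed.
* Gut-wall clearance of systemically circulating drug is neglected
  (documented above), so F_G is purely a first-pass quantity.
* Accuracy statistics for the curated archetypes are directional
  reproductions of the published model-refinement pattern, not re-creations
  of any proprietary simulator's absolute values.
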