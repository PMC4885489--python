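"""Minimal-PBPK core: enzyme turnover, clearances, and simulation oracles."""

import math

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from cypinduct.calibration import SiteInduction
from cypinduct.pbpk import (
    CompoundProfile,
    DoseRegimen,
    EnzymeState,
    MBIParams,
    PathwayClearance,
    SimOptions,
    SystemParameters,
    baseline_metrics,
    clearance_terms,
    enzyme_rhs,
    extract_metrics,
    mechanistic_static_ratio,
    simulate,
)
from cypinduct.synthetic import make_compound_profile, victim_profile


def _simple(name="drug", **kw):
    base = dict(name=name, mw=300.0, fu_p=1.0, bp=1.0, fu_gut=1.0, kp_liver=1.0,
                ka=0.0, fa=0.0, vss=50 / 70, cl_renal=0.0)
    base.update(kw)
    return CompoundProfile(**base)


class TestEnzymeRhs:
    def test_baseline_steady_state(self):
        es = EnzymeState()
        assert enzyme_rhs(es, 0.0, 0.0, SiteInduction(16, 0.32, 16, 0.32)) == (0.0, 0.0)

    def test_steady_state_fold_at_half_maximal_exposure(self):
        # constant I = IndC_50 with Ind_max 16 -> steady fold 8.5
        es = EnzymeState(enz_act_h=8.5, enz_act_g=8.5)
        dh, dg = enzyme_rhs(es, 0.32, 0.32, SiteInduction(16, 0.32, 16, 0.32))
        assert dh == pytest.approx(0.0, abs=1e-12)
        assert dg == pytest.approx(0.0, abs=1e-12)

    def test_relaxation_matches_scalar_linear_ode_closed_form(self):
        # Enz(t)/E0 = 7.364 - 6.364*exp(-kdeg t) for I = 3.2, Ind_max 8,
        # IndC_50 0.32, kdeg 0.03/h; checked at t = 1/kdeg
        kdeg = 0.03
        ind = SiteInduction(8, 0.32, 8, 0.32)

        def rhs(t, y):
            es = EnzymeState(enz_act_h=y[0], enz_act_g=y[1], kdeg_h=kdeg, kdeg_g=kdeg)
            return enzyme_rhs(es, 3.2, 3.2, ind)

        t_star = 1 / kdeg
        sol = solve_ivp(rhs, (0, t_star), [1.0, 1.0], rtol=1e-12, atol=1e-14,
                        dense_output=True)
        ss = 1 + 7 * 3.2 / (0.32 + 3.2)
        expected = ss - (ss - 1) * math.exp(-kdeg * t_star)
        assert abs(sol.sol(t_star)[0] - expected) < 1e-9

    def test_mbi_adds_first_order_loss(self):
        es = EnzymeState()
        mbi = MBIParams(ki_app_uM=1.0, kinact_per_h=0.1)
        dh, _ = enzyme_rhs(es, 1.0, 0.0, None, mbi)
        assert dh == pytest.approx(-0.05)  # kinact * I/(KI+I) at Enz=1

    def test_negative_concentration_raises(self):
        with pytest.raises(ValueError):
            enzyme_rhs(EnzymeState(), -0.1, 0.0, None)


class TestClearanceTerms:
    victim = _simple(elimination=(
        PathwayClearance("CYP3A4", "liver", clu_int=100.0),
        PathwayClearance("other", "liver", clu_int=50.0),
    ))

    def test_baseline_equals_input_clearances(self):
        clu_h, clu_g = clearance_terms(self.victim, EnzymeState())
        assert clu_h == pytest.approx(150.0)
        assert clu_g == 0.0

    def test_cyp3a4_pathways_scale_linearly_with_enzyme(self):
        es = EnzymeState(enz_act_h=2.0)
        clu_h, _ = clearance_terms(self.victim, es)
        assert clu_h == pytest.approx(250.0)

    def test_three_fold_enzyme_and_fm(self):
        es = EnzymeState(enz_act_h=3.0)
        clu_h, _ = clearance_terms(self.victim, es)
        assert clu_h == pytest.approx(350.0)
        m = baseline_metrics(self.victim, SystemParameters())
        assert m["fm_cyp3a4"] == pytest.approx(2 / 3)

    def test_competitive_inhibition_divisor(self):
        clu_h, _ = clearance_terms(self.victim, EnzymeState(), i_liver_u=2.0,
                                   ki_u={"CYP3A4": 1.0})
        assert clu_h == pytest.approx(100.0 / 3 + 50.0)

    def test_no_ki_means_no_inhibition(self):
        clu_h, _ = clearance_terms(self.victim, EnzymeState(), i_liver_u=100.0)
        assert clu_h == pytest.approx(150.0)

    def test_unknown_enzyme_raises(self):
        bad = _simple(elimination=(PathwayClearance("CYP9Z9", "liver", clu_int=1.0),))
        with pytest.raises(ValueError, match="unknown enzyme"):
            clearance_terms(bad, EnzymeState())


class TestSimulateOracles:
    def test_iv_bolus_auc_equals_dose_over_clearance(self, system):
        prof = _simple(cl_renal=10.0)
        sim = simulate([prof], [DoseRegimen("drug", 1.0, "iv_bolus")], system)
        assert sim["drug"].auc_0_inf == pytest.approx(0.1, rel=1e-3)

    def test_iv_infusion_auc_equals_dose_over_clearance(self, system):
        prof = _simple(cl_renal=10.0)
        sim = simulate([prof], [DoseRegimen("drug", 1.0, "iv_infusion",
                                            infusion_duration_h=2.0)], system)
        assert sim["drug"].auc_0_inf == pytest.approx(0.1, rel=1e-3)

    def test_well_stirred_hepatic_clearance(self, system):
        # fu_B*CLu_int = 100, Q_h = 90 -> CL_blood = 90*100/190 = 47.37
        prof = _simple(vss=1.0, elimination=(
            PathwayClearance("CYP3A4", "liver", clu_int=100.0),))
        sim = simulate([prof], [DoseRegimen("drug", 10.0, "iv_bolus")], system)
        cl = 10.0 / sim["drug"].auc_0_inf
        assert cl == pytest.approx(90 * 100 / 190, rel=1e-2)
        assert sim["drug"].fh == pytest.approx(90 / 190, rel=1e-2)
        assert sim["drug"].fm_cyp3a4 == pytest.approx(1.0, rel=1e-6)

    def test_gut_extraction_midpoint(self, system):
        # fu_gut*CLu_int_G = Q_gut -> F_G = 0.5
        prof = _simple(ka=1.5, fa=1.0, vss=1.0, fu_p=0.1, elimination=(
            PathwayClearance("CYP3A4", "liver", clu_int=100.0),
            PathwayClearance("CYP3A4", "gut", clu_int=18.0)))
        sim = simulate([prof], [DoseRegimen("drug", 10.0, "oral")], system)
        assert sim["drug"].fg == pytest.approx(0.5, rel=1e-6)

    def test_michaelis_menten_linear_limit_matches_clint(self, system):
        lin = _simple(fu_p=0.5, vss=1.0, elimination=(
            PathwayClearance("CYP3A4", "liver", clu_int=50.0),))
        km_uM = 100.0
        vmax = 50.0 * km_uM * 300 / 1000  # CLu_int * Km in mg/L
        mm = _simple(fu_p=0.5, vss=1.0, elimination=(
            PathwayClearance("CYP3A4", "liver", vmax=vmax, km_u=km_uM),))
        a = simulate([lin], [DoseRegimen("drug", 1.0, "iv_bolus")], system)
        b = simulate([mm], [DoseRegimen("drug", 1.0, "iv_bolus")], system)
        assert b["drug"].auc_0_inf == pytest.approx(a["drug"].auc_0_inf, rel=1e-2)
        # saturation raises dose-normalized exposure
        c = simulate([mm], [DoseRegimen("drug", 500.0, "iv_bolus")], system)
        assert c["drug"].auc_0_inf / 500 > b["drug"].auc_0_inf / 1 * 1.01

    def test_unknown_regimen_compound_raises(self, system):
        with pytest.raises(ValueError, match="unknown compound"):
            simulate([_simple()], [DoseRegimen("ghost", 1.0, "iv_bolus")], system)


class TestInteractionInvariants:
    def test_ddi_ratio_is_one_without_induction_or_inhibition(
            self, system, midazolam, tight_opts):
        inert = make_compound_profile("rifampicin_like", induction=None)
        opts = SimOptions(rtol=1e-7, atol=1e-10, horizon_h=24.0)
        alone = simulate([midazolam], [DoseRegimen("midazolam", 5.0, "oral")],
                         system, opts)
        both = simulate([midazolam, inert],
                        [DoseRegimen("midazolam", 5.0, "oral"),
                         DoseRegimen("rifampicin_like", 600.0, "oral", 24.0, 2)],
                        system, opts)
        assert both["midazolam"].auc_0_t == pytest.approx(
            alone["midazolam"].auc_0_t, rel=1e-6)

    def test_enzyme_trajectory_bounded_under_pure_induction(self, system):
        perp = make_compound_profile("rifampicin_like",
                                     induction=SiteInduction(16, 0.32, 16, 0.32))
        sim = simulate([perp], [DoseRegimen("rifampicin_like", 600.0, "oral", 24.0, 7)],
                       system, SimOptions(rtol=1e-6, atol=1e-9))
        assert np.all(sim.enz_h >= 1.0 - 1e-6)
        assert np.all(sim.enz_h <= 16.0 + 1e-6)
        assert np.all(sim.enz_g >= 1.0 - 1e-6)
        assert np.all(sim.enz_g <= 16.0 + 1e-6)

    def test_mass_balance_absorbed_amount_bounded_by_fa_dose(self, system):
        prof = _simple(ka=1.0, fa=0.7, vss=1.0, fu_p=0.5, elimination=(
            PathwayClearance("CYP3A4", "liver", clu_int=50.0),))
        sim = simulate([prof], [DoseRegimen("drug", 10.0, "oral")], system)
        r = sim["drug"]
        # cumulative systemic + eliminated amounts can never exceed Fa*Dose
        total_cleared = 10.0 * 0.7
        assert r.auc_0_inf * baseline_metrics(prof, system)["cl_total_plasma"] \
            <= total_cleared * 1.01

    def test_autoinduction_lowers_trough_on_multiple_dosing(self, system):
        auto = make_compound_profile("autoinducer")
        sim = simulate([auto], [DoseRegimen("autoinducer", 400.0, "oral", 12.0, 14)],
                       system, SimOptions(rtol=1e-5, atol=1e-8))
        r = sim["autoinducer"]
        trough = lambda day: np.interp(day * 24 - 0.01, r.t, r.conc_plasma)
        assert trough(7) < trough(1)
        assert r.enz_h[-1] > 1.1  # its own CYP3A4 pool is induced


class TestStaticDynamicEquivalence:
    def test_clamped_dynamic_ratio_matches_static_net_effect(self, system, midazolam):
        # perpetrator clamped at constant unbound exposure for >= 10/kdeg
        perp = make_compound_profile("rifampicin_like",
                                     induction=SiteInduction(16, 0.32, 16, 0.32))
        i_liver, i_gut = 0.5, 2.0  # µM unbound
        t_eq = 10 / system.kdeg_h
        opts = SimOptions(rtol=1e-6, atol=1e-9)
        ctrl = simulate([midazolam], [DoseRegimen("midazolam", 5.0, "oral")],
                        system, opts)
        ind = simulate([midazolam, perp],
                       [DoseRegimen("midazolam", 5.0, "oral", start_time_h=t_eq)],
                       system, SimOptions(rtol=1e-6, atol=1e-9,
                                          clamped={"rifampicin_like": (i_liver, i_gut)},
                                          horizon_h=t_eq + 48.0))
        dyn = ctrl["midazolam"].auc_0_inf / ind["midazolam"].auc_0_inf
        fold_h = 1 + 15 * i_liver / (0.32 + i_liver)
        fold_g = 1 + 15 * i_gut / (0.32 + i_gut)
        stat = mechanistic_static_ratio(midazolam, system, fold_h, fold_g, "oral")
        assert dyn == pytest.approx(stat, rel=0.02)

    def test_oral_ratio_exceeds_iv_ratio_for_same_folds(self, system, midazolam):
        oral = mechanistic_static_ratio(midazolam, system, 4.0, 4.0, "oral")
        iv = mechanistic_static_ratio(midazolam, system, 4.0, 4.0, "iv_bolus")
        assert oral > iv > 1.0


class TestExtractMetrics:
    def test_constant_profile_trapezoid(self):
        from cypinduct.pbpk import SimulationResult
        t = np.linspace(0, 10, 101)
        res = SimulationResult(
            name="x", t=t, conc_plasma=np.ones_like(t), conc_liver=np.ones_like(t),
            conc_portal_plasma=np.ones_like(t), conc_enterocyte=np.ones_like(t),
            enz_h=np.ones_like(t), enz_g=np.ones_like(t), mw=300.0,
            auc_0_t=10.0, auc_0_inf=None, auc_tail_ok=False, cmax=1.0,
            fg=None, fh=None, fm_cyp3a4=None)
        m = extract_metrics(res, interval=(0, 10))
        assert m["auc_0_t"] == pytest.approx(10.0)
        assert not m["auc_tail_identifiable"]  # flat profile has no terminal slope

    def test_monoexponential_tail_extrapolation(self):
        from cypinduct.pbpk import SimulationResult
        t = np.linspace(0, 30, 301)
        c = 2.0 * np.exp(-0.2 * t)
        res = SimulationResult(
            name="x", t=t, conc_plasma=c, conc_liver=c, conc_portal_plasma=c,
            conc_enterocyte=c, enz_h=np.ones_like(t), enz_g=np.ones_like(t),
            mw=300.0, auc_0_t=0.0, auc_0_inf=None, auc_tail_ok=False,
            cmax=2.0, fg=None, fh=None, fm_cyp3a4=None)
        m = extract_metrics(res)
        assert m["auc_0_inf"] == pytest.approx(10.0, rel=5e-3)

    def test_interval_outside_profile_raises(self):
        from cypinduct.pbpk import SimulationResult
        t = np.linspace(0, 5, 6)
        res = SimulationResult(
            name="x", t=t, conc_plasma=np.ones_like(t), conc_liver=np.ones_like(t),
            conc_portal_plasma=np.ones_like(t), conc_enterocyte=np.ones_like(t),
            enz_h=np.ones_like(t), enz_g=np.ones_like(t), mw=300.0,
            auc_0_t=5.0, auc_0_inf=None, auc_tail_ok=False, cmax=1.0,
            fg=None, fh=None, fm_cyp3a4=None)
        with pytest.raises(ValueError):
            extract_metrics(res, interval=(10, 20))


class TestProfileValidation:
    def test_fraction_bounds_enforced(self):
        with pytest.raises(ValueError, match="fu_p"):
            _simple(fu_p=1.2)
        with pytest.raises(ValueError, match="Fa"):
            _simple(fa=-0.1)

    def test_pathway_mode_exclusivity(self):
        with pytest.raises(ValueError):
            PathwayClearance("CYP3A4", "liver", clu_int=1.0, vmax=1.0, km_u=1.0)
        with pytest.raises(ValueError):
            PathwayClearance("CYP3A4", "liver")

    def test_gut_pathway_must_be_linear(self):
        with pytest.raises(ValueError, match="liver"):
            PathwayClearance("CYP3A4", "gut", vmax=10.0, km_u=1.0)
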