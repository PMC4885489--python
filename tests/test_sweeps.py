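"""Scenario and sensitivity sweeps at reference-subject scale."""

import numpy as np
import pytest
from dataclasses import replace

from cypinduct.evaluate import (
    DDIResult,
    gmfe,
    pool_trials,
    scenario_sweep,
    sensitivity_sweep,
    summarize_accuracy,
)
from cypinduct.io import load_rifampicin_studies
from cypinduct.pbpk import DoseRegimen, SimOptions
from cypinduct.synthetic import (
    SyntheticStudySpec,
    make_compound_profile,
    make_study_table,
    victim_profile,
)
from cypinduct.trial import CVConfig, DDIStudyDesign


@pytest.fixture(scope="module")
def small_design():
    return DDIStudyDesign(
        study_id="S1",
        perpetrator=(DoseRegimen("rifampicin", 600.0, "oral", 24.0, 5),),
        victim=DoseRegimen("midazolam", 15.0, "oral"),
        stagger_h=17.0, n_subjects=1, n_trials=1)


class TestScenarioSweep:
    def test_predicted_ratio_monotone_in_ind_max(self, small_design, fast_opts,
                                                 no_cv):
        perp = make_compound_profile("rifampicin_like")
        mdz = victim_profile("midazolam")
        summary, per_study = scenario_sweep(
            [(small_design, mdz)], perp,
            models=["model_A", "model_F", "model_C", "model_G"],
            seed=1, options=fast_opts, cv=no_cv)
        ratios = per_study.set_index("model")["predicted_ratio"]
        assert ratios["model_A"] < ratios["model_F"] < ratios["model_C"] \
            < ratios["model_G"]

    def test_deterministic_under_seed(self, small_design, fast_opts):
        perp = make_compound_profile("rifampicin_like")
        mdz = victim_profile("midazolam")
        _, a = scenario_sweep([(small_design, mdz)], perp, models=["model_A"],
                              seed=7, options=fast_opts)
        _, b = scenario_sweep([(small_design, mdz)], perp, models=["model_A"],
                              seed=7, options=fast_opts)
        assert a["predicted_ratio"].tolist() == b["predicted_ratio"].tolist()

    def test_degenerate_sweep_perfect_predictions(self):
        # when predicted == observed for every study, GMFE is 1 and every
        # prediction sits inside the acceptance limits
        from cypinduct.evaluate import ObservedStudy
        results = []
        for k, r in enumerate((1.5, 3.0, 12.0)):
            obs = ObservedStudy(study_id=f"D{k}", victim="midazolam",
                                route="oral", n=10, auc_control=r,
                                auc_induced=1.0, ratio_printed=r)
            results.append(DDIResult(study_id=f"D{k}", model="model_X",
                                     trial_ratios={0: r}, pooled_ratio=r,
                                     pooled_cmax_ratio=None, subject_ratios=[r],
                                     observed=obs))
        for s in summarize_accuracy(results, "model_X"):
            assert s.gmfe == pytest.approx(1.0)
            assert s.percent_within_limits == 100.0


class TestSensitivitySweep:
    def test_fu_gut_insensitive_when_exposure_saturates_induction(
            self, small_design, fast_opts):
        # when unbound enterocyte exposure far exceeds IndC_50 under either
        # binding assumption, the stimulus is saturated and the gut-binding
        # assumption barely moves the prediction
        from cypinduct.calibration import SiteInduction
        # IndC_50 three orders of magnitude below the trough unbound
        # concentration at either binding assumption
        perp = make_compound_profile(
            "rifampicin_like", induction=SiteInduction(16, 0.001, 16, 0.001))
        mdz = victim_profile("midazolam")
        # perpetrator dosing continues through the victim window so unbound
        # exposure stays far above IndC_50 at either binding assumption
        design = replace(
            small_design,
            perpetrator=(DoseRegimen("rifampicin", 600.0, "oral", 24.0, 7),),
            stagger_h=-31.0)
        df = sensitivity_sweep("fu_gut_in", [0.19, 1.0], design, mdz, perp,
                               options=fast_opts)
        r = df.set_index("value")["predicted_ratio"]
        assert abs(r[1.0] / r[0.19] - 1) < 0.10

    def test_fu_gut_matters_when_exposure_straddles_indc50(
            self, small_design, fast_opts):
        # complementary case: at the base potency the trough unbound
        # concentrations sit near IndC_50, so gut binding is influential
        perp = make_compound_profile("rifampicin_like")
        mdz = victim_profile("midazolam")
        df = sensitivity_sweep("fu_gut_in", [0.19, 1.0], small_design, mdz, perp,
                               options=fast_opts)
        r = df.set_index("value")["predicted_ratio"]
        assert r[1.0] > r[0.19]

    def test_kdeg_sets_onset_kinetics_not_steady_state(self, system):
        # halving kdeg doubles the time to 90% of steady state but leaves the
        # steady-state fold unchanged (linear turnover ODE)
        from cypinduct.calibration import SiteInduction
        from cypinduct.pbpk import SimOptions, SystemParameters, simulate
        perp = make_compound_profile("rifampicin_like",
                                     induction=SiteInduction(16, 0.32, 16, 0.32))
        folds, t90s = [], []
        for kdeg in (0.03, 0.015):
            sysk = SystemParameters(kdeg_h=kdeg, kdeg_g=kdeg)
            sim = simulate([perp], [], sysk,
                           SimOptions(clamped={perp.name: (3.2, 3.2)},
                                      horizon_h=40 / kdeg,
                                      points_per_segment=4000))
            ss = sim.enz_h[-1]
            target = 1 + 0.9 * (ss - 1)
            t90s.append(sim.t[np.argmax(sim.enz_h >= target)])
            folds.append(ss)
        assert folds[0] == pytest.approx(folds[1], rel=1e-3)
        assert t90s[1] == pytest.approx(2 * t90s[0], rel=0.05)

    def test_single_value_sweep_equals_plain_run(self, small_design, fast_opts,
                                                 no_cv):
        from cypinduct.trial import run_study
        perp = make_compound_profile("rifampicin_like")
        mdz = victim_profile("midazolam")
        df = sensitivity_sweep("kdeg_h", [0.0193], small_design, mdz, perp,
                               options=fast_opts)
        run = run_study(small_design, mdz, perp, cv=no_cv, options=fast_opts)
        assert df["predicted_ratio"][0] == pytest.approx(run.pooled_ratio(),
                                                         rel=1e-9)

    def test_invalid_parameter_raises(self, small_design, fast_opts):
        perp = make_compound_profile("rifampicin_like")
        mdz = victim_profile("midazolam")
        with pytest.raises(ValueError):
            sensitivity_sweep("vmax", [1.0], small_design, mdz, perp)
        with pytest.raises(ValueError):
            sensitivity_sweep("kdeg_h", [-1.0], small_design, mdz, perp)


class TestPipelineClosure:
    def test_gmfe_approaches_one_as_observation_noise_vanishes(self, fast_opts):
        # generate synthetic studies at truth parameters, then predict them
        # with the same truth configuration: the loop closes exactly at zero
        # noise and degrades gracefully with noise
        spec0 = SyntheticStudySpec(n_studies=3, n_subjects=1, obs_noise_cv=0.0,
                                   seed=11)
        designs, observed, truth = make_study_table(spec0, options=fast_opts)
        perp = make_compound_profile("rifampicin_like",
                                     induction=truth["induction"])
        from cypinduct.trial import CVConfig, run_study
        no_cv = CVConfig(cv_cyp3a4_h=0, cv_cyp3a4_g=0, cv_clu=0, cv_ka=0,
                         cv_vss=0, cv_qh=0, bw_cv=0)
        pairs = []
        for design, obs in zip(designs, observed):
            victim = make_compound_profile(obs.victim)
            run = run_study(design, victim, perp, cv=no_cv, options=fast_opts)
            pairs.append((run.pooled_ratio(), obs.ratio_recip))
        assert gmfe(pairs) == pytest.approx(1.0, abs=1e-6)

    def test_misspecified_ind_max_biases_predictions_low(self, fast_opts):
        from cypinduct.calibration import SiteInduction
        from cypinduct.trial import CVConfig, run_study
        spec0 = SyntheticStudySpec(n_studies=2, n_subjects=1, obs_noise_cv=0.0,
                                   seed=13)
        designs, observed, truth = make_study_table(spec0, options=fast_opts)
        half = SiteInduction(8.0, 0.32, 8.0, 0.32)  # half the truth efficacy
        perp = make_compound_profile("rifampicin_like", induction=half)
        no_cv = CVConfig(cv_cyp3a4_h=0, cv_cyp3a4_g=0, cv_clu=0, cv_ka=0,
                         cv_vss=0, cv_qh=0, bw_cv=0)
        for design, obs in zip(designs, observed):
            victim = make_compound_profile(obs.victim)
            run = run_study(design, victim, perp, cv=no_cv, options=fast_opts)
            assert run.pooled_ratio() < obs.ratio_recip
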