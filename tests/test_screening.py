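import copy

import numpy as np
import pytest

from crcscreen.natural_history import CohortConfig, PersonState, simulate_cohort
from crcscreen.screening import (
    StrategySpec,
    SurveillanceSchedule,
    TestCharacteristics as TChar,
    fit_colo_switch_strategy,
    next_action,
    perform_endoscopy,
    perform_stool_test,
    run_strategy,
    single_phase_strategy,
)
from crcscreen.states import DiseaseState, Event, Modality
from crcscreen.states import TestReason as Reason
from crcscreen.tables import NaturalHistoryParams

from test_natural_history import ZERO_LT, ZERO_SURV, flat_params


def perfect_tests():
    colo = TChar("colonoscopy", 1.0, 1.0, 1.0, 1.0, 0.0)
    fit = TChar("fit", 1.0, 1.0, 1.0, 1.0)
    return {"colonoscopy": colo, "fit": fit}


class TestNextAction:
    def test_before_start_age(self):
        strat = single_phase_strategy("FIT", "fit", 24)
        p = PersonState(age_months=44 * 12 + 11, next_screen_month=45 * 12)
        assert next_action(p, strat, p.age_months) == "none"

    def test_lockout_after_negative_colonoscopy(self):
        strat = single_phase_strategy("Colo", "colonoscopy", 120)
        p = PersonState(age_months=50 * 12, next_screen_month=50 * 12)
        colo = perfect_tests()["colonoscopy"]

        class NeverDetect:
            def random(self):
                return 0.99

        perform_endoscopy(p, colo, Reason.SCREEN, NeverDetect())
        assert p.next_screen_month == 60 * 12
        assert next_action(p, strat, 59 * 12) == "none"
        assert next_action(p, strat, 60 * 12) == "offer_screen"

    def test_surveillance_supersedes_and_stops(self):
        strat = single_phase_strategy("Colo", "colonoscopy", 120)
        p = PersonState(age_months=60 * 12, in_surveillance=True)
        assert next_action(p, strat, 60 * 12) == "offer_surveillance_colo"
        assert next_action(p, strat, 86 * 12) == "none"

    def test_clinical_person_rejected(self):
        strat = single_phase_strategy("FIT", "fit", 24)
        p = PersonState(state=DiseaseState.CLIN_LOCAL, age_months=600, dx_month=590, dx_stage=0)
        with pytest.raises(ValueError):
            next_action(p, strat, 600)


class TestStoolTest:
    def test_perfect_specificity_never_positive_on_healthy(self):
        t = TChar("fit", 0.1, 0.2, 0.7, 1.0)
        rng = np.random.default_rng(0)
        assert not any(
            perform_stool_test(PersonState(), t, rng) for _ in range(200)
        )

    def test_perfect_sensitivity_always_positive_on_preclinical(self):
        t = TChar("fit", 0.1, 0.2, 1.0, 0.9)
        rng = np.random.default_rng(0)
        p = PersonState(state=DiseaseState.PRECLIN_LOCAL)
        assert all(perform_stool_test(p, t, rng) for _ in range(200))

    def test_false_positive_rate_binomial(self):
        t = TChar("fit", 0.1, 0.2, 0.7, 0.95)
        rng = np.random.default_rng(7)
        n = 10_000
        pos = sum(perform_stool_test(PersonState(), t, rng) for _ in range(n))
        se = np.sqrt(0.05 * 0.95 * n)
        assert abs(pos - 0.05 * n) < 3 * se

    def test_endoscopic_modality_rejected(self):
        colo = perfect_tests()["colonoscopy"]
        with pytest.raises(ValueError):
            perform_stool_test(PersonState(), colo, np.random.default_rng(0))


class TestEndoscopy:
    def test_hr_removal_enrolls_surveillance(self):
        p = PersonState(state=DiseaseState.ADENOMA_HR, age_months=600)
        res = perform_endoscopy(
            p, perfect_tests()["colonoscopy"], Reason.SCREEN, np.random.default_rng(0)
        )
        assert res.finding == "HR"
        assert p.state == DiseaseState.HEALTHY
        assert p.in_surveillance

    def test_distal_only_reach_misses_out_of_reach_lesion(self):
        sig = TChar(
            "sigmoidoscopy", 1.0, 1.0, 1.0, 1.0, 0.0, whole_colon=False, distal_fraction=0.0
        )
        p = PersonState(state=DiseaseState.ADENOMA_HR, age_months=600)
        res = perform_endoscopy(p, sig, Reason.SCREEN, np.random.default_rng(0))
        assert res.finding == "none"
        assert p.state == DiseaseState.ADENOMA_HR

    def test_zero_complication_probability(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            p = PersonState(state=DiseaseState.HEALTHY, age_months=600)
            res = perform_endoscopy(p, perfect_tests()["colonoscopy"], Reason.SCREEN, rng)
            assert not res.complication

    def test_detected_cancer_becomes_clinical_same_stage(self):
        p = PersonState(state=DiseaseState.PRECLIN_REGIONAL, age_months=700)
        res = perform_endoscopy(
            p, perfect_tests()["colonoscopy"], Reason.FOLLOWUP, np.random.default_rng(0)
        )
        assert res.finding == "CRC" and res.stage == 1
        assert p.state == DiseaseState.CLIN_REGIONAL
        assert p.screen_detected and p.dx_month == 700

    def test_stool_modality_rejected(self):
        fit = perfect_tests()["fit"]
        with pytest.raises(ValueError):
            perform_endoscopy(PersonState(), fit, Reason.SCREEN, np.random.default_rng(0))


class TestRunStrategy:
    def test_adherence_zero_equals_natural_history(self, bundle):
        cfg = CohortConfig(n=3000, seed=21)
        s0 = copy.deepcopy(bundle.strategies["FIT"])
        s0.adherence = 0.0
        nh = simulate_cohort(cfg, bundle.truth_params, bundle.lifetable, bundle.survival, tests=bundle.tests)
        a0 = run_strategy(cfg, bundle.truth_params, bundle.lifetable, bundle.survival, s0, bundle.tests)
        assert nh.events.equals(a0.events)

    def test_biennial_grid_yields_16_offers(self):
        # immortal, disease-free cohort with full adherence: FIT at 45,47,...,75
        cfg = CohortConfig(n=50, seed=1)
        strat = single_phase_strategy("FIT", "fit", 24, adherence=1.0)
        tests = {
            "colonoscopy": TChar("colonoscopy", 0.9, 0.9, 0.9, 1.0, 0.0),
            "fit": TChar("fit", 0.0, 0.0, 0.0, 1.0),
        }
        tr = run_strategy(cfg, flat_params(), ZERO_LT, ZERO_SURV, strat, tests)
        ev = tr.events
        fit_tests = ev[(ev["event"] == int(Event.TEST)) & (ev["modality"] == int(Modality.FIT))]
        assert len(fit_tests) == 16 * cfg.n
        ages = sorted(fit_tests["age_months"].unique())
        assert ages == [45 * 12 + 24 * k for k in range(16)]

    def test_switch_strategy_offer_schedule(self):
        cfg = CohortConfig(n=20, seed=2)
        strat = fit_colo_switch_strategy(adherence=1.0)
        tests = {
            "colonoscopy": TChar("colonoscopy", 0.0, 0.0, 0.0, 1.0, 0.0),
            "fit": TChar("fit", 0.0, 0.0, 0.0, 1.0),
        }
        tr = run_strategy(cfg, flat_params(), ZERO_LT, ZERO_SURV, strat, tests)
        ev = tr.events[tr.events["event"] == int(Event.TEST)]
        fit_ages = sorted(ev[ev["modality"] == int(Modality.FIT)]["age_months"].unique())
        colo_ages = sorted(ev[ev["modality"] == int(Modality.COLONOSCOPY)]["age_months"].unique())
        assert fit_ages == [540, 564, 588]
        # negative colonoscopies lock out 120 months, matching the q10y grid
        assert colo_ages == [600, 720, 840]

    def test_followup_colonoscopies_bounded_by_stool_tests(self, bundle):
        cfg = CohortConfig(n=3000, seed=23)
        tr = run_strategy(
            cfg, bundle.truth_params, bundle.lifetable, bundle.survival,
            bundle.strategies["FIT"], bundle.tests,
        )
        ev = tr.events
        stool = ((ev["event"] == int(Event.TEST)) & (ev["modality"] == int(Modality.FIT))).sum()
        fu = (
            (ev["event"] == int(Event.TEST))
            & (ev["modality"] == int(Modality.COLONOSCOPY))
            & (ev["reason"] == int(Reason.FOLLOWUP))
        ).sum()
        assert 0 < fu <= stool

    def test_no_offers_outside_age_window(self, bundle):
        cfg = CohortConfig(n=3000, seed=23)
        tr = run_strategy(
            cfg, bundle.truth_params, bundle.lifetable, bundle.survival,
            bundle.strategies["FIT"], bundle.tests,
        )
        ev = tr.events
        firstline = ev[(ev["event"] == int(Event.TEST)) & (ev["reason"] == int(Reason.SCREEN))]
        assert firstline["age_months"].min() >= 45 * 12
        assert firstline["age_months"].max() <= 75 * 12
        surv = ev[(ev["event"] == int(Event.TEST)) & (ev["reason"] == int(Reason.SURVEILLANCE))]
        if len(surv):
            assert surv["age_months"].max() <= 85 * 12

    def test_zero_sensitivity_perfect_specificity_keeps_nh_disease_outcomes(self, bundle):
        cfg = CohortConfig(n=3000, seed=29)
        tests = copy.deepcopy(bundle.tests)
        for t in tests.values():
            t.sens_adenoma_lr = t.sens_adenoma_hr = t.sens_crc = 0.0
            t.specificity = 1.0
            t.complication_prob = 0.0
        strat = copy.deepcopy(bundle.strategies["FIT"])
        nh = simulate_cohort(cfg, bundle.truth_params, bundle.lifetable, bundle.survival, tests=tests)
        tr = run_strategy(cfg, bundle.truth_params, bundle.lifetable, bundle.survival, strat, tests)
        disease_kinds = [int(Event.ADENOMA_ONSET), int(Event.STAGE_TRANSITION),
                         int(Event.SYMPTOMATIC_DX), int(Event.DEATH_CRC), int(Event.DEATH_OTHER)]
        a = nh.events[nh.events["event"].isin(disease_kinds)].reset_index(drop=True)
        b = tr.events[tr.events["event"].isin(disease_kinds)].reset_index(drop=True)
        assert a.equals(b)
        # the trace still records the (all-negative) stool tests
        assert (tr.events["event"] == int(Event.TEST)).sum() > (nh.events["event"] == int(Event.TEST)).sum()

    def test_perfect_screen_clears_prevalent_disease(self):
        # onset only before 45; perfect FIT + colonoscopy at full adherence:
        # everything prevalent at the first offer is removed or diagnosed,
        # so no lesions and no symptomatic diagnoses can exist afterwards
        values = {
            "p_adenoma_onset": np.array([1.5e-3, 0.0]),
            "p_LR_to_HR": np.array([3e-3]),
            "p_HR_to_preclin": np.array([2e-3]),
            "p_local_to_regional": np.array([3e-2]),
            "p_regional_to_distant": np.array([4e-2]),
            "p_detect_local": np.array([5e-3]),
            "p_detect_regional": np.array([3e-2]),
            "p_detect_distant": np.array([8e-2]),
        }
        edges = {k: (np.array([20, 45, 100]) if k == "p_adenoma_onset" else np.array([20, 100]))
                 for k in values}
        params = NaturalHistoryParams(values=values, edges=edges)
        cfg = CohortConfig(n=2000, seed=31)
        strat = single_phase_strategy("FIT", "fit", 24, adherence=1.0)
        tr = run_strategy(cfg, params, ZERO_LT, ZERO_SURV, strat, perfect_tests())
        first_offer_cycle = (45 - 20) * 12
        assert tr.occupancy[first_offer_cycle + 2 :, 1:6].sum() == 0
        sym = tr.events[tr.events["event"] == int(Event.SYMPTOMATIC_DX)]
        assert (sym["age_months"] <= 45 * 12).all()

    def test_sigmoidoscopies_counted_separately(self, bundle):
        cfg = CohortConfig(n=3000, seed=37)
        tr = run_strategy(
            cfg, bundle.truth_params, bundle.lifetable, bundle.survival,
            bundle.strategies["Sig"], bundle.tests,
        )
        ev = tr.events
        n_sig = ((ev["event"] == int(Event.TEST)) & (ev["modality"] == int(Modality.SIGMOIDOSCOPY))).sum()
        assert n_sig > 0
        # colonoscopy counter excludes sigmoidoscopies
        n_colo_events = ((ev["event"] == int(Event.TEST)) & (ev["modality"] == int(Modality.COLONOSCOPY))).sum()
        assert tr.n_colonoscopies() == n_colo_events
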