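import numpy as np
import pandas as pd
import pytest

from crcscreen.natural_history import (
    CohortConfig,
    CohortTrace,
    PersonState,
    cohort_matrix_oracle,
    incidence_and_stage_summary,
    nh_forward_summary,
    simulate_cohort,
    step_person,
)
from crcscreen.states import DiseaseState, Event
from crcscreen.tables import Lifetable, NaturalHistoryParams, StageSurvival


def flat_params(**overrides):
    names = (
        "p_adenoma_onset",
        "p_LR_to_HR",
        "p_HR_to_preclin",
        "p_local_to_regional",
        "p_regional_to_distant",
        "p_detect_local",
        "p_detect_regional",
        "p_detect_distant",
    )
    values = {n: np.array([overrides.get(n, 0.0)]) for n in names}
    return NaturalHistoryParams(values=values)


ZERO_LT = Lifetable(np.zeros(101))
ZERO_SURV = StageSurvival(np.zeros((3, 10)))


def empty_events():
    return pd.DataFrame(
        {
            "person_id": np.array([], dtype=np.int64),
            "age_months": np.array([], dtype=np.int32),
            "event": np.array([], dtype=np.int8),
            "stage": np.array([], dtype=np.int8),
            "modality": np.array([], dtype=np.int8),
            "reason": np.array([], dtype=np.int8),
        }
    )


class TestStepPerson:
    def test_null_dynamics(self):
        p = PersonState()
        out = step_person(p, flat_params(), ZERO_LT, ZERO_SURV, np.random.default_rng(0))
        assert out.state == DiseaseState.HEALTHY
        assert out.age_months == p.age_months + 1

    def test_cancer_mortality_window_closes(self):
        # 121 months after diagnosis a 0.9/yr cancer hazard no longer applies
        surv = StageSurvival(np.full((3, 10), 0.9))
        rng = np.random.default_rng(1)
        p = PersonState(
            state=DiseaseState.CLIN_DISTANT, age_months=60 * 12 + 121, dx_month=60 * 12, dx_stage=2
        )
        for _ in range(200):
            p = step_person(p, flat_params(), ZERO_LT, surv, rng)
        assert p.state == DiseaseState.CLIN_DISTANT

    def test_cancer_mortality_applies_inside_window(self):
        surv = StageSurvival(np.full((3, 10), 0.9))
        rng = np.random.default_rng(1)
        p = PersonState(
            state=DiseaseState.CLIN_DISTANT, age_months=60 * 12, dx_month=60 * 12 - 1, dx_stage=2
        )
        for _ in range(60):
            p = step_person(p, flat_params(), ZERO_LT, surv, rng)
            if p.state == DiseaseState.DEATH_CRC:
                break
        assert p.state == DiseaseState.DEATH_CRC

    def test_exit_frequencies_match_probabilities(self):
        # single-cycle multinomial from PreclinLocal: detect 0.3, progress 0.2
        params = flat_params(p_detect_local=0.3, p_local_to_regional=0.2)
        rng = np.random.default_rng(42)
        n = 5000
        counts = {DiseaseState.CLIN_LOCAL: 0, DiseaseState.PRECLIN_REGIONAL: 0}
        for _ in range(n):
            p = PersonState(state=DiseaseState.PRECLIN_LOCAL, age_months=600)
            out = step_person(p, params, ZERO_LT, ZERO_SURV, rng)
            if out.state in counts:
                counts[out.state] += 1
        for st, prob in ((DiseaseState.CLIN_LOCAL, 0.3), (DiseaseState.PRECLIN_REGIONAL, 0.2)):
            se = np.sqrt(prob * (1 - prob) * n)
            assert abs(counts[st] - prob * n) < 3 * se

    def test_dead_person_rejected(self):
        p = PersonState(state=DiseaseState.DEATH_OTHER)
        with pytest.raises(ValueError):
            step_person(p, flat_params(), ZERO_LT, ZERO_SURV, np.random.default_rng(0))


class TestSimulateCohort:
    def test_null_cohort_survives_with_empty_log(self):
        cfg = CohortConfig(n=1000, seed=5)
        tr = simulate_cohort(cfg, flat_params(), ZERO_LT, ZERO_SURV)
        assert tr.occupancy[-1, 0] == 1000
        assert len(tr.events) == 0

    def test_seed_determinism(self, bundle):
        cfg = CohortConfig(n=2000, seed=99)
        a = simulate_cohort(cfg, bundle.truth_params, bundle.lifetable, bundle.survival)
        b = simulate_cohort(cfg, bundle.truth_params, bundle.lifetable, bundle.survival)
        assert a.events.equals(b.events)
        np.testing.assert_array_equal(a.occupancy, b.occupancy)

    def test_conservation(self, nh_trace):
        assert (nh_trace.occupancy.sum(axis=1) == nh_trace.n).all()

    def test_no_resurrection_and_monotone_event_ages(self, nh_trace):
        ev = nh_trace.events
        # event ages are non-decreasing per person
        assert (ev.groupby("person_id")["age_months"].apply(lambda s: s.is_monotonic_increasing)).all()
        # a death event is the last event for its person
        deaths = ev[ev["event"].isin([int(Event.DEATH_CRC), int(Event.DEATH_OTHER)])]
        last = ev.groupby("person_id")["age_months"].max()
        assert (deaths.set_index("person_id")["age_months"] == last[deaths["person_id"]].values).all()
        assert not deaths["person_id"].duplicated().any()

    def test_crc_death_only_after_diagnosis(self, nh_trace):
        died_crc = np.flatnonzero(nh_trace.death_cause == 0)
        assert (nh_trace.dx_month[died_crc] >= 0).all()
        assert (nh_trace.death_month[died_crc] > nh_trace.dx_month[died_crc]).all()


class TestOracle:
    def test_identity_dynamics_constant_occupancy(self):
        cfg = CohortConfig(n=10)
        res = cohort_matrix_oracle(cfg, flat_params(), ZERO_LT, ZERO_SURV)
        assert (res.occupancy[:, 0] == 1.0).all()

    def test_two_state_hand_arithmetic(self):
        # Healthy -> LR at p=0.5/month, 2 cycles: occupancy (0.25, 0.75)
        cfg = CohortConfig(n=10)
        res = cohort_matrix_oracle(cfg, flat_params(p_adenoma_onset=0.5), ZERO_LT, ZERO_SURV)
        assert res.occupancy[2, 0] == pytest.approx(0.25)
        assert res.occupancy[2, 1] == pytest.approx(0.75)

    def test_microsimulation_converges_to_oracle(self, bundle):
        from scipy import stats

        n = 20_000
        cfg = CohortConfig(n=n, seed=17)
        orc = cohort_matrix_oracle(cfg, bundle.truth_params, bundle.lifetable, bundle.survival)
        tr = simulate_cohort(cfg, bundle.truth_params, bundle.lifetable, bundle.survival)
        p = orc.occupancy
        pv = np.minimum(
            stats.binom.cdf(tr.occupancy, n, p), stats.binom.sf(tr.occupancy - 1, n, p)
        )
        # family-wise exact binomial test at the 3-sigma level
        alpha = 2 * stats.norm.sf(3.0)
        sidak = 1.0 - (1.0 - alpha) ** (1.0 / p.size)
        assert (pv >= sidak / 2).all()

    def test_forward_summary_matches_oracle_diagnosis_flow(self, bundle):
        cfg = CohortConfig(n=10)
        orc = cohort_matrix_oracle(cfg, bundle.truth_params, bundle.lifetable, bundle.survival)
        fwd = nh_forward_summary(bundle.truth_params, bundle.lifetable)
        assert fwd.lifetime_incidence == pytest.approx(float(orc.dx_inflow.sum()), rel=1e-9)


class TestIncidenceSummary:
    def _trace(self, n, dx_month, dx_stage, death_month, death_cause):
        return CohortTrace(
            n=n,
            n_cycles=960,
            occupancy=np.zeros((961, 11), dtype=np.int64),
            events=empty_events(),
            death_month=death_month,
            death_cause=death_cause,
            dx_month=dx_month,
            dx_stage=dx_stage,
            screen_detected=np.zeros(n, dtype=bool),
            seed=0,
        )

    def test_zero_diagnoses_flagged(self):
        n = 50
        tr = self._trace(
            n,
            np.full(n, -1, np.int64),
            np.full(n, -1, np.int8),
            np.full(n, -1, np.int64),
            np.full(n, -1, np.int8),
        )
        s = incidence_and_stage_summary(tr)
        assert s.empty
        assert s.stage_distribution is None
        assert (s.incidence_per_100k == 0).all()

    def test_hand_built_incidence_arithmetic(self):
        # 2 diagnoses among 100 persons, each contributing one person-year
        # in the 60-64 band -> 2,000 per 100,000 person-years
        n = 100
        dx_month = np.full(n, -1, np.int64)
        dx_stage = np.full(n, -1, np.int8)
        death_month = np.full(n, 61 * 12, np.int64)
        death_cause = np.full(n, 1, np.int8)
        dx_month[:2] = 61 * 12
        dx_stage[:2] = 0
        tr = self._trace(n, dx_month, dx_stage, death_month, death_cause)
        s = incidence_and_stage_summary(tr)
        assert s.incidence_band(60, 65) == pytest.approx(2000.0)

    def test_fixture_incidence_monotone_with_age(self, bundle):
        s = nh_forward_summary(bundle.truth_params, bundle.lifetable)
        edges = np.arange(30, 85, 5)
        inc = s.incidence_per_100k(edges)
        assert (np.diff(inc) > 0).all()
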