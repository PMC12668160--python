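import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from crcscreen.calibration import (
    CALIBRATED_PARAMS,
    AnnealSchedule,
    CalibrationTargets,
    anneal,
    objective,
    propose,
    validate_calibration,
)
from crcscreen.natural_history import NHForwardSummary, nh_forward_summary
from crcscreen.synthetic import make_lifetable, make_truth_and_targets


@pytest.fixture(scope="module")
def problem():
    lt = make_lifetable("mid", 0)
    truth, targets = make_truth_and_targets(0, "dr", lt)
    return truth, targets, (lambda p: nh_forward_summary(p, lt))


def fixed_summary(value: float) -> NHForwardSummary:
    """A forward stub whose every incidence band evaluates to `value`."""
    py = np.ones(80)
    dx = np.zeros((80, 3))
    dx[:, 0] = value / 1e5  # per person-year -> `value` per 100k
    return NHForwardSummary(py, dx, np.zeros(80))


class TestObjective:
    def test_self_consistency_zero(self, problem):
        truth, targets, fwd = problem
        assert objective(truth, targets, fwd) == pytest.approx(0.0, abs=1e-15)

    def test_single_target_arithmetic(self):
        targets = CalibrationTargets(incidence=[(50, 55, 100.0, 1.0)])
        score = objective(None, targets, lambda p: fixed_summary(150.0))
        assert score == pytest.approx(0.25)

    @given(st.floats(min_value=0.1, max_value=10.0))
    @settings(max_examples=20, deadline=None)
    def test_score_linear_in_weights(self, problem, factor):
        truth, targets, fwd = problem
        perturbed = truth.with_vector(truth.to_vector() * 0.8)
        base = objective(perturbed, targets, fwd)
        scaled = CalibrationTargets(
            incidence=[(lo, hi, v, w * factor) for lo, hi, v, w in targets.incidence],
            prevalence=[(a, v, w * factor) for a, v, w in targets.prevalence],
            stage=(targets.stage[0], targets.stage[1] * factor),
        )
        assert objective(perturbed, scaled, fwd) == pytest.approx(base * factor, rel=1e-9)

    def test_out_of_horizon_target_rejected(self):
        with pytest.raises(ValueError, match="horizon"):
            CalibrationTargets(incidence=[(95, 105, 10.0, 1.0)])
        with pytest.raises(ValueError, match="horizon"):
            CalibrationTargets(prevalence=[(110, 0.3, 1.0)])

    def test_stage_target_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum"):
            CalibrationTargets(stage=(np.array([0.5, 0.2, 0.2]), 1.0))


class TestPropose:
    def test_zero_step_identity(self, problem):
        truth, _, _ = problem
        out = propose(truth, 0.0, CALIBRATED_PARAMS, np.random.default_rng(0))
        np.testing.assert_array_equal(out.to_vector(), truth.to_vector())

    def test_logit_arithmetic(self, problem):
        truth, _, _ = problem
        p = truth.copy()
        p.values["p_HR_to_preclin"] = np.array([0.5])

        class StepRng:
            def normal(self, loc, scale, size=None):
                return np.full(size, 0.1) if size else 0.1

        out = propose(p, 1.0, ("p_HR_to_preclin",), StepRng())
        assert out.values["p_HR_to_preclin"][0] == pytest.approx(1 / (1 + np.exp(-0.1)))

    def test_unmasked_parameters_bit_identical(self, problem):
        truth, _, _ = problem
        out = propose(truth, 0.3, ("p_adenoma_onset",), np.random.default_rng(3))
        for name in truth.values:
            if name != "p_adenoma_onset":
                np.testing.assert_array_equal(out.values[name], truth.values[name])

    def test_outputs_stay_inside_unit_interval(self, problem):
        truth, _, _ = problem
        rng = np.random.default_rng(5)
        current = truth
        for _ in range(2000):
            current = propose(current, 1.5, CALIBRATED_PARAMS, rng)
            v = current.to_vector(CALIBRATED_PARAMS)
            assert ((v > 0) & (v < 1)).all()

    def test_empty_mask_rejected(self, problem):
        truth, _, _ = problem
        with pytest.raises(ValueError, match="mask"):
            propose(truth, 0.1, (), np.random.default_rng(0))


class TestAnneal:
    def test_zero_iterations_returns_initial(self, problem):
        truth, targets, fwd = problem
        start = truth.with_vector(truth.to_vector() * 0.7)
        sched = AnnealSchedule(max_iter=0, seed=1)
        res = anneal(targets, sched, start, forward=fwd)
        np.testing.assert_array_equal(res.best_params.to_vector(), start.to_vector())
        assert res.best_objective == pytest.approx(objective(start, targets, fwd))

    def test_seed_determinism(self, problem):
        truth, targets, fwd = problem
        start = truth.with_vector(truth.to_vector() * 1.3)
        sched = AnnealSchedule(max_iter=60, seed=7)
        a = anneal(targets, sched, start, forward=fwd)
        b = anneal(targets, sched, start, forward=fwd)
        np.testing.assert_array_equal(a.trajectory, b.trajectory)
        np.testing.assert_array_equal(a.best_params.to_vector(), b.best_params.to_vector())

    def test_best_so_far_non_increasing(self, problem):
        truth, targets, fwd = problem
        start = truth.with_vector(truth.to_vector() * 1.5)
        res = anneal(targets, AnnealSchedule(max_iter=120, seed=3), start, forward=fwd)
        running = np.minimum.accumulate(res.trajectory)
        assert (np.diff(running) <= 0).all()
        assert res.best_objective == pytest.approx(running[-1])

    def test_greedy_limit_only_improves(self, problem):
        # at zero temperature the incumbent objective never worsens
        truth, targets, fwd = problem
        start = truth.with_vector(truth.to_vector() * 1.4)
        stages = [(CALIBRATED_PARAMS, ("incidence", "prevalence", "stage"), {"initial_temp": 0.0})]
        res = anneal(
            targets, AnnealSchedule(max_iter=150, seed=11), start, stage_masks=stages, forward=fwd
        )
        assert (np.diff(res.trajectory) <= 1e-12).all()

    def test_stage_masks_touch_only_their_parameters(self, problem):
        truth, targets, fwd = problem
        start = truth.with_vector(truth.to_vector(("p_adenoma_onset",)) * 1.6, ("p_adenoma_onset",))
        stages = [(("p_adenoma_onset",), ("prevalence",))]
        res = anneal(
            targets, AnnealSchedule(max_iter=80, seed=2), start, stage_masks=stages, forward=fwd
        )
        for name in truth.values:
            if name != "p_adenoma_onset":
                np.testing.assert_array_equal(res.best_params.values[name], start.values[name])

    def test_recovery_improves_objective(self, problem):
        truth, targets, fwd = problem
        rng = np.random.default_rng(4)
        tv = truth.to_vector(CALIBRATED_PARAMS)
        start = truth.with_vector(tv * rng.uniform(0.5, 2.0, len(tv)), CALIBRATED_PARAMS)
        before = objective(start, targets, fwd)
        res = anneal(targets, AnnealSchedule(max_iter=300, seed=4), start, forward=fwd)
        assert res.best_objective < before / 10


class TestValidateCalibration:
    def test_holdout_equals_fit_targets(self, problem):
        truth, targets, fwd = problem
        res = anneal(targets, AnnealSchedule(max_iter=0, seed=1), truth, forward=fwd)
        report = validate_calibration(res, targets, forward=fwd)
        assert not report.attrs["empty"]
        assert (report["relative_deviation"].abs() < 1e-9).all()
        assert not report["flagged"].any()

    def test_empty_holdout_flagged(self, problem):
        truth, targets, fwd = problem
        res = anneal(targets, AnnealSchedule(max_iter=0, seed=1), truth, forward=fwd)
        report = validate_calibration(res, CalibrationTargets(), forward=fwd)
        assert report.attrs["empty"]
        assert len(report) == 0
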