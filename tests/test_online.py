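"""Online control simulation: trial state machine, gating, dwell/timeout
logic, block composition and outcome measures."""

import numpy as np
import pytest

import myogrid as mg
from myogrid.core import GESTURES, WRISTS, TaskLabel
from myogrid.online import (GATING_WINDOWS, SubjectPolicy, TrialRecord,
                            TrialResult, TrialSpec, count_dwellings,
                            outcome_measures, run_block, run_trial)
from myogrid.synth import SimulationConfig, default_gesture_model

from conftest import make_small_session


@pytest.fixture(scope="module")
def trial_env():
    """Small-montage environment for stub-predictor trials."""
    layout = mg.build_layout(4, 4, 4, 10.0)
    config = SimulationConfig()
    model = default_gesture_model(layout)
    mvc = 10.0  # nominal reference for gating; stub trials don't train
    return layout, config, model, mvc


def _spec(gesture="PG", wrist="neutral", level="low"):
    return TrialSpec.for_level(TaskLabel(gesture, wrist), level)


class TestRunTrial:
    def test_oracle_predictor_succeeds_after_exactly_2s(self, trial_env):
        layout, config, model, _ = trial_env
        # steady mid-window activation, no delay, predictor always on target
        policy = SubjectPolicy(reaction_delay_s=0.0, activation_sigma=0.0,
                               off_target_prob=0.0)
        mvc = 10.0
        res = run_trial(None, mg.all_select(layout), _spec(), policy, config,
                        layout, model, mvc, seed=0, predictor=lambda X: "PG")
        assert res.success
        assert res.completion_time_s == pytest.approx(2.0)
        assert res.dwellings == 0

    def test_never_correct_predictor_fails_at_10s(self, trial_env):
        layout, config, model, mvc = trial_env
        policy = SubjectPolicy(0.0, 0.0, 0.0)
        res = run_trial(None, mg.all_select(layout), _spec(), policy, config,
                        layout, model, mvc, seed=0, predictor=lambda X: "HO")
        assert not res.success
        assert res.completion_time_s is None
        assert len(res.predictions) == 80  # ran to the full 10 s

    def test_activation_below_window_gives_no_valid_ticks(self, trial_env):
        layout, config, model, mvc = trial_env
        # subject never reacts -> activation stays at rest, out of the window
        policy = SubjectPolicy(reaction_delay_s=1e9, activation_sigma=0.0,
                               off_target_prob=0.0)
        res = run_trial(None, mg.all_select(layout), _spec(), policy, config,
                        layout, model, mvc, seed=0, predictor=lambda X: "PG")
        assert not res.success
        assert not any(res.in_gate)

    def test_same_seed_reproducible(self, trial_env):
        layout, config, model, mvc = trial_env
        policy = SubjectPolicy()
        a = run_trial(None, mg.all_select(layout), _spec(), policy, config,
                      layout, model, mvc, seed=4, predictor=lambda X: "PG")
        b = run_trial(None, mg.all_select(layout), _spec(), policy, config,
                      layout, model, mvc, seed=4, predictor=lambda X: "PG")
        assert a.predictions == b.predictions
        assert a.activation == b.activation

    def test_low_force_gate_lower_bound_is_10_percent_mvc(self, trial_env):
        """Sweep the produced activation across the low window boundary."""
        layout, config, model, _ = trial_env
        lo, hi = GATING_WINDOWS["low"]
        assert lo == 0.10
        from myogrid.online import _gate_check
        spec = _spec(level="low")
        for est, ok in ((0.05, False), (0.099, False), (0.10, True),
                        (0.20, True), (0.35, True), (0.36, False)):
            assert _gate_check(est, spec) is ok


class TestDwellings:
    def test_hand_counted_transitions(self):
        preds = ["A", "A", "B", "A"]
        assert count_dwellings(preds, [True] * 4) == 2

    def test_out_of_window_gap_is_not_a_change(self):
        preds = ["A", "A", "B", "B"]
        gate = [True, True, False, True]
        # A->B happens across an out-of-window tick: not counted
        assert count_dwellings(preds, gate) == 0

    def test_changes_only_between_consecutive_in_window_ticks(self):
        preds = ["A", "B", "B", "C"]
        gate = [True, True, False, True]
        assert count_dwellings(preds, gate) == 1  # only A->B


class TestOutcomeMeasures:
    def _rec(self, success, t, dw):
        return TrialRecord("SFS", "PG", "neutral", "low",
                           TrialResult(success, t, dw))

    def test_rate_time_and_dwellings(self):
        recs = [self._rec(True, 3.0, 2), self._rec(True, 5.0, 4),
                self._rec(False, None, 7)]
        m = outcome_measures(recs)
        assert m["completion_rate_pct"] == pytest.approx(100 * 2 / 3)
        assert m["median_completion_time_s"] == 4.0
        assert m["median_dwellings"] == 3.0  # failures excluded

    def test_15_of_21_gives_71_4_percent(self):
        recs = [self._rec(i < 15, 4.0 if i < 15 else None, 1) for i in range(21)]
        assert outcome_measures(recs)["completion_rate_pct"] == pytest.approx(
            71.4, abs=0.05)

    def test_no_successes_reports_rate_with_undefined_times(self):
        recs = [self._rec(False, None, 3)] * 4
        m = outcome_measures(recs)
        assert m["completion_rate_pct"] == 0.0
        assert m["median_completion_time_s"] is None
        assert m["median_dwellings"] is None

    def test_grouping_by_method(self):
        recs = [self._rec(True, 2.0, 0),
                TrialRecord("CIRC", "PG", "neutral", "low",
                            TrialResult(False, None, 1))]
        m = outcome_measures(recs, by="method")
        assert m["SFS"]["completion_rate_pct"] == 100.0
        assert m["CIRC"]["completion_rate_pct"] == 0.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            outcome_measures([])


@pytest.fixture(scope="module")
def block_env():
    """Small session with trained ALL-channel model (shared across tests)."""
    ses = make_small_session(seed=6)
    fm = mg.session_features(ses)
    model = mg.fit_on_channels(fm)
    cs = mg.all_select(ses.layout)
    return ses, {"ALL": model}, {"ALL": cs}


class TestRunBlock:
    def test_covers_gesture_wrist_method_product_once(self, block_env):
        ses, models, sets = block_env
        recs = run_block(ses, models, sets, "low", seed=1)
        combos = [(r.method, r.gesture, r.wrist) for r in recs]
        assert len(combos) == 24
        assert set(combos) == {("ALL", g, w) for g in GESTURES for w in WRISTS}

    def test_same_seed_identical_results(self, block_env):
        ses, models, sets = block_env
        a = run_block(ses, models, sets, "low", seed=2)
        b = run_block(ses, models, sets, "low", seed=2)
        assert [(r.gesture, r.wrist, r.result.success, r.result.completion_time_s)
                for r in a] == \
               [(r.gesture, r.wrist, r.result.success, r.result.completion_time_s)
                for r in b]

    def test_levels_change_gate_not_targets(self, block_env):
        ses, models, sets = block_env
        lo = run_block(ses, models, sets, "low", seed=3)
        mo = run_block(ses, models, sets, "moderate", seed=3)
        assert [(r.gesture, r.wrist) for r in lo] == [(r.gesture, r.wrist) for r in mo]
        assert {r.level for r in lo} == {"low"}
        assert {r.level for r in mo} == {"moderate"}
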