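"""Fitts'-law game: difficulty indices, target generation, trial dynamics."""

import math

import numpy as np
import pytest

from myofitts.fitts import (
    ConfusionUser,
    GameConfig,
    Target,
    TargetConfiguration,
    confusion_from_accuracy,
    index_of_difficulty,
    intended_gesture,
    make_game,
    run_game,
    run_trial,
    score_session,
    step_cursor,
)
from myofitts.simulate import ONLINE_GESTURES

LABELS = list(ONLINE_GESTURES)


def perfect_user(seed=0):
    return ConfusionUser(np.eye(5), LABELS, seed=seed)


class TestIndexOfDifficulty:
    def test_boundary_values(self):
        assert index_of_difficulty(0.0, 5.0) == 0.0
        assert index_of_difficulty(7.0, 7.0) == 1.0

    def test_strictly_increasing_in_distance(self):
        ids = [index_of_difficulty(d, 10.0) for d in (10, 30, 50, 100, 200)]
        assert all(a < b for a, b in zip(ids, ids[1:]))

    def test_strictly_decreasing_in_width(self):
        ids = [index_of_difficulty(50.0, w) for w in (2, 5, 10, 20, 40)]
        assert all(a > b for a, b in zip(ids, ids[1:]))

    def test_zero_width_rejected(self):
        with pytest.raises(ValueError):
            index_of_difficulty(50.0, 0.0)


class TestMakeGame:
    def test_game_has_24_targets_four_per_configuration(self):
        game = make_game(GameConfig(seed=11))
        assert len(game.targets) == 24
        counts = {}
        for t in game.targets:
            key = (t.configuration.distance, t.configuration.width)
            counts[key] = counts.get(key, 0) + 1
        assert counts == {
            (50, 5): 4, (50, 10): 4, (50, 20): 4,
            (100, 5): 4, (100, 10): 4, (100, 20): 4,
        }

    def test_target_numbers_are_a_permutation(self):
        game = make_game(GameConfig(seed=3))
        assert sorted(t.number for t in game.targets) == list(range(1, 25))

    def test_same_seed_reproduces_order_and_positions(self):
        a = make_game(GameConfig(seed=9))
        b = make_game(GameConfig(seed=9))
        assert [t.number for t in a.targets] == [t.number for t in b.targets]
        assert all(ta.center == tb.center for ta, tb in zip(a.targets, b.targets))

    def test_centres_lie_at_configured_distance(self):
        for t in make_game(GameConfig(seed=5)).targets:
            r = math.hypot(*t.center)
            assert r == pytest.approx(t.configuration.distance, abs=1e-9)

    def test_targets_fit_inside_grid(self):
        for seed in range(5):
            for t in make_game(GameConfig(seed=seed)).targets:
                half = t.configuration.width / 2
                assert max(abs(t.center[0]), abs(t.center[1])) + half <= 110 + 1e-9

    def test_axis_aligned_placement_sits_on_an_axis(self):
        for t in make_game(GameConfig(seed=2, placement="axis_aligned")).targets:
            assert min(abs(t.center[0]), abs(t.center[1])) < 1e-9


class TestStepCursor:
    cfg = GameConfig()

    def test_extension_moves_plus_x_one_step(self):
        assert step_cursor((0.0, 0.0), "wrist_extension", self.cfg) == (
            pytest.approx(110 / 28), 0.0)

    def test_rest_is_stationary(self):
        assert step_cursor((13.0, -4.0), "rest", self.cfg) == (13.0, -4.0)

    def test_28_steps_reach_grid_edge_then_clamp(self):
        pos = (0.0, 0.0)
        for _ in range(28):
            pos = step_cursor(pos, "wrist_extension", self.cfg)
        assert pos[0] == pytest.approx(110.0)
        assert step_cursor(pos, "wrist_extension", self.cfg)[0] <= 110.0

    def test_unknown_gesture_rejected(self):
        with pytest.raises(ValueError, match="unknown gesture"):
            step_cursor((0.0, 0.0), "thumbs_up", self.cfg)

    def test_intent_moves_along_larger_axis_and_rests_inside(self):
        target = Target(1, TargetConfiguration(50, 10, (1, 2, 3, 4)), (30.0, -40.0))
        assert intended_gesture((0.0, 0.0), target, self.cfg) == "closed_hand"
        assert intended_gesture((30.0, -38.0), target, self.cfg) == "rest"


class TestRunTrial:
    def test_perfect_user_succeeds_on_every_target(self):
        game = make_game(GameConfig(seed=21))
        trials = run_game(game, perfect_user())
        assert all(t.success for t in trials)

    def test_axis_aligned_completion_time_matches_minimum_path(self):
        """For axis-placed targets a perfect user needs exactly
        ceil((D - W/2)/step) motion ticks plus the 1 s dwell."""
        cfg = GameConfig(seed=13, placement="axis_aligned")
        for t in run_game(make_game(cfg), perfect_user()):
            d, w = t.configuration.distance, t.configuration.width
            bound = math.ceil((d - w / 2) / cfg.step) * cfg.tick + cfg.dwell
            assert t.completion_time == pytest.approx(bound)

    def test_random_angle_time_respects_geometric_lower_bound(self):
        cfg = GameConfig(seed=17)
        game = make_game(cfg)
        for t, target in zip(run_game(game, perfect_user()), game.targets):
            half = target.configuration.width / 2
            manhattan = max(0.0, abs(target.center[0]) - half) + max(
                0.0, abs(target.center[1]) - half)
            min_ticks = math.ceil(manhattan / cfg.step - 1e-9)
            assert t.completion_time >= min_ticks * cfg.tick + cfg.dwell - 1e-9

    def test_always_rest_user_times_out(self):
        target = make_game(GameConfig(seed=1)).targets[0]
        stuck = ConfusionUser(
            np.tile([0, 0, 0, 0, 1.0], (5, 1)), LABELS, seed=0)
        trial = run_trial(target, stuck, GameConfig(seed=1))
        assert not trial.success
        assert trial.completion_time is None
        assert len(trial.cursor_trace) == 101  # origin + 100 ticks of 0.2 s

    def test_trace_starts_at_origin_and_is_reproducible(self):
        cfg = GameConfig(seed=6)
        target = make_game(cfg).targets[0]
        a = run_trial(target, ConfusionUser(confusion_from_accuracy(0.8), LABELS, 5), cfg)
        b = run_trial(target, ConfusionUser(confusion_from_accuracy(0.8), LABELS, 5), cfg)
        assert a.cursor_trace[0] == (0, 0.0, 0.0)
        assert a.cursor_trace == b.cursor_trace
        assert a.classified == b.classified


class TestScoreSession:
    def _trial(self, success, ct, d=50.0, w=5.0):
        from myofitts.fitts import TrialResult

        conf = TargetConfiguration(d, w, (1, 2, 3, 4))
        return TrialResult(
            target_number=1, configuration=conf, success=success,
            completion_time=ct, cursor_trace=[(0, 0.0, 0.0)],
            intended=[], classified=[],
        )

    def test_single_success_ratio(self):
        conf = TargetConfiguration(30.0, 10.0, (1, 2, 3, 4))  # ID = 2 bits
        from myofitts.fitts import TrialResult

        trial = TrialResult(1, conf, True, 4.0, [(0, 0.0, 0.0)], [], [])
        m = score_session([trial])
        assert m.throughput == pytest.approx(0.5)
        assert m.completion_rate == 100.0

    def test_23_of_24_completion_rate(self):
        trials = [self._trial(True, 3.0)] * 23 + [self._trial(False, None)]
        assert score_session(trials).completion_rate == pytest.approx(95.83, abs=0.01)

    def test_all_failures_undefined_throughput(self):
        trials = [self._trial(False, None)] * 4
        m = score_session(trials)
        assert m.completion_rate == 0.0
        assert math.isnan(m.throughput)

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            score_session([])

    def test_throughput_drops_with_smaller_steps(self):
        """A perfect user transmits less information per second when each
        classification moves the cursor less."""
        tps = []
        for step in (110 / 28, 110 / 56):
            cfg = GameConfig(seed=30, step=step)
            m = score_session(run_game(make_game(cfg), perfect_user()))
            tps.append(m.throughput)
        assert tps[0] > tps[1]


class TestConfusionMatrixValidation:
    def test_rows_must_sum_to_one(self):
        bad = np.full((5, 5), 0.1)
        with pytest.raises(ValueError, match="sum to 1"):
            ConfusionUser(bad, LABELS)

    def test_confusion_from_accuracy_rows_normalise(self):
        C = confusion_from_accuracy(0.7)
        assert np.allclose(C.sum(axis=1), 1.0)
        assert np.allclose(np.diag(C), 0.7)
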