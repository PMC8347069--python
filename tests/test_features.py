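"""Feature pipeline: trimming, windowing, and the six time-domain features."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from myofitts.features import (
    FeatureConfig,
    WindowingConfig,
    build_feature_table,
    extract_features,
    mean_subtract,
    segment,
    trim_event,
)


def naive_features(x, zc_t=0.0, ssc_t=0.0, wamp_t=0.0):
    """Independent loop-based oracle computed straight from the definitions."""
    n = len(x)
    zc = sum(
        1 for i in range(n - 1)
        if x[i] * x[i + 1] < 0 and abs(x[i] - x[i + 1]) >= zc_t
    )
    rms = (sum(v * v for v in x) / n) ** 0.5
    mav = sum(abs(v) for v in x) / n
    wl = sum(abs(x[i + 1] - x[i]) for i in range(n - 1))
    ssc = sum(
        1 for i in range(1, n - 1)
        if (x[i] - x[i - 1]) * (x[i] - x[i + 1]) > 0
        and max(abs(x[i] - x[i - 1]), abs(x[i] - x[i + 1])) >= ssc_t
    )
    wamp = sum(1 for i in range(n - 1) if abs(x[i + 1] - x[i]) >= wamp_t)
    return [zc, rms, mav, wl, ssc, wamp]


class TestTrim:
    def test_six_second_event_trims_to_four(self):
        """A 6 s event at 2048 Hz (12288 samples) keeps the central 8192."""
        x = np.arange(12288.0)
        out = trim_event(x, 1.0, 2048.0)
        assert len(out) == 8192
        assert out[0] == 2048.0

    def test_zero_trim_is_identity(self):
        x = np.arange(100.0)
        assert np.array_equal(trim_event(x, 0.0, 2048.0), x)

    def test_event_shorter_than_two_trims_errors(self):
        with pytest.raises(ValueError, match="too short"):
            trim_event(np.zeros(3072), 1.0, 2048.0)  # 1.5 s event, 1 s trim


class TestMeanSubtract:
    def test_constant_channel_becomes_zero(self):
        x = np.full((50, 3), 7.5)
        assert not np.any(mean_subtract(x))

    def test_zero_mean_input_unchanged(self, rng):
        x = rng.standard_normal((64, 2))
        x -= x.mean(axis=0)
        assert np.allclose(mean_subtract(x), x)

    def test_output_column_means_are_zero(self, rng):
        out = mean_subtract(rng.uniform(-5, 5, (500, 4)))
        assert np.all(np.abs(out.mean(axis=0)) < 1e-9)

    def test_empty_input_errors(self):
        with pytest.raises(ValueError):
            mean_subtract(np.empty((0, 4)))


class TestSegment:
    def test_default_windowing_of_trimmed_event(self):
        """8192 samples at 2048 Hz with 200/50 ms -> 26 windows of 410."""
        wins = segment(np.zeros(8192), WindowingConfig(), 2048.0)
        assert wins.shape == (26, 410)

    def test_exactly_one_window(self):
        wins = segment(np.zeros(410), WindowingConfig(), 2048.0)
        assert wins.shape[0] == 1

    def test_disjoint_windows_with_zero_overlap(self):
        cfg = WindowingConfig(window_ms=100, overlap_ms=0)
        w = cfg.window_samples(1000.0)
        wins = segment(np.arange(3 * w, dtype=float), cfg, 1000.0)
        assert wins.shape[0] == 3
        assert wins[1][0] == w

    def test_short_signal_warns_and_returns_empty(self):
        with pytest.warns(UserWarning, match="shorter"):
            wins = segment(np.zeros(100), WindowingConfig(), 2048.0)
        assert wins.shape[0] == 0

    @given(length=st.integers(min_value=410, max_value=30000))
    @settings(max_examples=50, deadline=None)
    def test_window_count_matches_closed_form(self, length):
        cfg = WindowingConfig()
        w, s = cfg.window_samples(2048.0), cfg.step_samples(2048.0)
        wins = segment(np.zeros(length), cfg, 2048.0)
        assert wins.shape[0] == (length - w) // s + 1

    def test_overlap_must_be_smaller_than_window(self):
        with pytest.raises(ValueError):
            WindowingConfig(window_ms=100, overlap_ms=100)


class TestExtractFeatures:
    def test_alternating_signal_by_hand(self):
        """x=[1,-1,1,-1]: ZC=3, RMS=1, MAV=1, WL=6, WAMP counts the 3 diffs."""
        out = extract_features(np.array([1.0, -1.0, 1.0, -1.0]))
        zc, rms, mav, wl, ssc, wamp = out
        assert (zc, rms, mav, wl) == (3, 1.0, 1.0, 6.0)
        assert wamp == 3

    def test_zigzag_has_all_interior_extrema(self):
        assert extract_features(np.array([0.0, 1.0, 0.0, 1.0, 0.0]))[4] == 3

    def test_agrees_with_naive_oracle(self, rng):
        for _ in range(50):
            x = rng.standard_normal(410)
            assert np.allclose(extract_features(x), naive_features(x.tolist()))

    def test_agrees_with_oracle_under_thresholds(self, rng):
        cfg = FeatureConfig(zc_threshold=0.3, ssc_threshold=0.2, wamp_threshold=0.5)
        for _ in range(20):
            x = rng.standard_normal(64)
            assert np.allclose(
                extract_features(x, cfg),
                naive_features(x.tolist(), 0.3, 0.2, 0.5),
            )

    def test_amplitude_features_scale_linearly(self, rng):
        x = rng.standard_normal(200)
        base = extract_features(x)
        scaled = extract_features(3.0 * x)
        assert np.allclose(scaled[1:4], 3.0 * base[1:4])  # RMS, MAV, WL

    def test_count_features_invariant_to_positive_scaling(self, rng):
        x = rng.standard_normal(200)
        base = extract_features(x)
        scaled = extract_features(5.0 * x)
        assert np.array_equal(scaled[[0, 4, 5]], base[[0, 4, 5]])  # ZC, SSC, WAMP

    def test_window_too_short_errors(self):
        with pytest.raises(ValueError, match="too short"):
            extract_features(np.array([1.0, 2.0]))

    @given(offset=st.floats(min_value=-10, max_value=10, allow_nan=False))
    @settings(max_examples=25, deadline=None)
    def test_mean_subtraction_cancels_channel_offset(self, offset):
        rng = np.random.default_rng(99)
        x = rng.standard_normal((410, 1))
        a = extract_features(mean_subtract(x)[:, 0])
        b = extract_features(mean_subtract(x + offset)[:, 0])
        assert np.allclose(a, b, atol=1e-9)


class TestBuildFeatureTable:
    def test_offline_table_dimensions(self, offline_table):
        """9 gestures x 4 reps x 26 windows = 936 rows x 24 feature columns."""
        assert offline_table.matrix.shape == (936, 24)
        assert len(offline_table.feature_columns) == 24

    def test_labels_inherited_and_balanced(self, offline_table):
        labels, counts = np.unique(offline_table.labels, return_counts=True)
        assert len(labels) == 9
        assert np.all(counts == 104)  # 4 reps x 26 windows

    def test_column_order_is_channel_major(self, offline_table):
        assert offline_table.feature_columns[:7] == [
            "ch1_zc", "ch1_rms", "ch1_mav", "ch1_wl", "ch1_ssc", "ch1_wamp",
            "ch2_zc",
        ]

    def test_single_event_session_has_constant_group(self, small_session):
        from myofitts.simulate import EmgSession

        one = EmgSession(
            samples=small_session.samples,
            sampling_rate=small_session.sampling_rate,
            events=small_session.events[:1],
            electrode_type=small_session.electrode_type,
            seed=small_session.seed,
            protocol=small_session.protocol,
        )
        table = build_feature_table(one)
        assert len(set(table.groups)) == 1

    def test_pipeline_is_deterministic(self, small_session):
        a = build_feature_table(small_session)
        b = build_feature_table(small_session)
        assert np.array_equal(a.matrix, b.matrix)

    def test_csv_round_trip(self, offline_table, tmp_path):
        from myofitts.features import FeatureTable

        offline_table.to_csv(tmp_path / "t.csv")
        back = FeatureTable.from_csv(tmp_path / "t.csv")
        assert np.allclose(back.matrix, offline_table.matrix)
        assert list(back.labels) == list(offline_table.labels)

    def test_trim_error_names_the_event(self, acq):
        from myofitts.simulate import EmgSession, GestureProtocol

        proto = GestureProtocol(gesture_labels=("g", "rest"), reps_per_gesture=1,
                                gesture_duration=6.0)
        ses = EmgSession(
            samples=np.random.default_rng(0).standard_normal((4096, 4)),
            sampling_rate=2048.0,
            events=[("g", 0, 3000)],  # under 2 s: cannot trim 1 s per end
            electrode_type="gel",
            seed=0,
            protocol=proto,
        )
        with pytest.raises(ValueError, match="event 0"):
            build_feature_table(ses)
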