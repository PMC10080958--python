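import numpy as np
import pytest

from retstim.eye_movement import (
    ClassifierConfig,
    EyeMovementInterval,
    classify_gaze,
    classify_segments,
    fixation_metrics,
    saccade_metrics,
    segment_piecewise_linear,
)
from retstim.session_io import gaze_to_degrees


def _classify_one(speed_dps, duration_s, prev=None, config=None):
    """Label a single synthetic segment of given slope and duration."""
    config = config or ClassifierConfig()
    dt = 0.02
    n = max(int(duration_s / dt), 12)
    t = np.arange(n) * dt
    y = np.column_stack([speed_dps * t, np.zeros(n)])
    seg = segment_piecewise_linear(t, y, config)
    return classify_segments(seg, config)


class TestSegmentation:
    def test_two_piece_linear(self):
        t = np.arange(100) * 0.02
        y = np.where(t < 1.0, 2.0 * t, 2.0 + 30.0 * (t - 1.0))
        seg = segment_piecewise_linear(t, np.column_stack([y, np.zeros(100)]))
        assert seg.n_segments == 2
        assert abs(seg.bounds[1] - 50) <= 1

    def test_constant_trace(self):
        t = np.arange(50) * 0.02
        seg = segment_piecewise_linear(t, np.zeros((50, 2)))
        assert seg.n_segments == 1
        assert np.allclose(seg.slopes, 0.0)

    def test_staircase_breakpoints(self):
        # 10 fixation/saccade steps; every onset/offset within 1 sample
        rng = np.random.default_rng(0)
        dt = 0.02
        pieces, truth_bounds, pos = [], [], 0.0
        for _ in range(10):
            n_fix = 12
            pieces.append(np.full(n_fix, pos) + rng.normal(0, 0.02, n_fix))
            truth_bounds.append(sum(len(p) for p in pieces))
            step = 3.0
            n_sac = 2
            flight = pos + np.linspace(0, step, n_sac + 2)[1:-1]
            pieces.append(flight)
            truth_bounds.append(sum(len(p) for p in pieces))
            pos += step
        y = np.concatenate(pieces)
        t = np.arange(y.size) * dt
        seg = segment_piecewise_linear(t, np.column_stack([y, np.zeros_like(y)]))
        assert seg.n_segments >= 11  # >= 10 breakpoints
        for tb in truth_bounds[:-1]:
            assert np.min(np.abs(seg.bounds - tb)) <= 1

    def test_too_short_trace(self):
        with pytest.raises(ValueError):
            segment_piecewise_linear(np.arange(5) * 0.02, np.zeros((5, 2)))


class TestClassification:
    def test_slow_segment_is_fixation(self):
        intervals = _classify_one(0.5, 0.3)
        assert intervals[0].label == "fixation"

    def test_fast_brief_segment_is_saccade(self):
        config = ClassifierConfig()
        dt = 0.02
        # fixation - brief 300 deg/s ramp - fixation
        y = np.concatenate([np.zeros(15), np.linspace(0, 12, 3)[1:], np.full(15, 12.0)])
        t = np.arange(y.size) * dt
        seg = segment_piecewise_linear(t, np.column_stack([y, np.zeros_like(y)]), config)
        labels = [iv.label for iv in classify_segments(seg, config)]
        assert "saccade" in labels

    def test_sustained_pursuit(self):
        intervals = _classify_one(5.0, 0.6)
        assert intervals[0].label == "smooth_pursuit"

    def test_pso_requires_preceding_saccade(self):
        config = ClassifierConfig()
        rng = np.random.default_rng(3)
        # mixture trace; property: no PSO without an immediately preceding saccade
        y = np.cumsum(rng.normal(0, 0.5, 400))
        t = np.arange(400) * 0.02
        seg = segment_piecewise_linear(t, np.column_stack([y, np.zeros(400)]), config)
        labels = [iv.label for iv in classify_segments(seg, config)]
        for i, lab in enumerate(labels):
            if lab == "pso":
                assert i > 0 and labels[i - 1] == "saccade"

    def test_deterministic(self, short_reading):
        session, _ = short_reading
        az, el, ok = gaze_to_degrees(session.gaze.gp3)
        valid = session.gaze.validity & ok
        a = classify_gaze(session.gaze.t, az, el, valid)
        b = classify_gaze(session.gaze.t, az, el, valid)
        assert [(iv.label, iv.start_s, iv.end_s) for iv in a] == [
            (iv.label, iv.start_s, iv.end_s) for iv in b
        ]

    def test_intervals_tile_without_overlap(self, short_reading):
        session, _ = short_reading
        az, el, ok = gaze_to_degrees(session.gaze.gp3)
        valid = session.gaze.validity & ok
        intervals = classify_gaze(session.gaze.t, az, el, valid)
        starts = np.array([iv.start_s for iv in intervals])
        ends = np.array([iv.end_s for iv in intervals])
        order = np.argsort(starts)
        assert (ends[order][:-1] <= starts[order][1:] + 1e-9).all()

    def test_viterbi_mode_runs(self):
        intervals = _classify_one(5.0, 0.6, config=ClassifierConfig(viterbi=True))
        assert intervals[0].label == "smooth_pursuit"


class TestAgreementWithGroundTruth:
    @pytest.mark.parametrize("kind", ["reading", "walking"])
    def test_sample_agreement(self, kind, short_reading, short_walking):
        session, truth = short_reading if kind == "reading" else short_walking
        az, el, ok = gaze_to_degrees(session.gaze.gp3)
        valid = session.gaze.validity & ok
        intervals = classify_gaze(session.gaze.t, az, el, valid)
        pred = np.full(session.gaze.t.size, None, dtype=object)
        for iv in intervals:
            pred[(session.gaze.t >= iv.start_s) & (session.gaze.t < iv.end_s)] = iv.label
        m = valid & (pred != None)  # noqa: E711
        agreement = (pred[m] == truth.sample_labels[m]).mean()
        assert agreement >= 0.90

        lab = truth.sample_labels.copy()
        lab[~valid] = "invalid"
        n_true = sum(
            1 for i in range(len(lab)) if lab[i] == "saccade" and (i == 0 or lab[i - 1] != "saccade")
        )
        n_pred = sum(1 for iv in intervals if iv.label == "saccade")
        assert abs(n_pred - n_true) <= 0.10 * n_true


class TestMetrics:
    def test_three_four_five(self):
        iv = EyeMovementInterval("saccade", 0.0, 0.02, 0.0, 5.0)
        amp, vel = saccade_metrics([iv])
        assert amp[0] == 5.0
        assert vel[0] == pytest.approx(250.0)

    def test_amplitude_from_components(self):
        assert np.hypot(3.0, 4.0) == 5.0  # the 3-4-5 identity the interval carries

    def test_pure_horizontal(self):
        iv = EyeMovementInterval("saccade", 0.0, 0.01, 0.0, 2.0)
        _, vel = saccade_metrics([iv])
        assert vel[0] == pytest.approx(200.0)

    def test_zero_displacement(self):
        iv = EyeMovementInterval("saccade", 0.0, 0.02, 0.0, 0.0)
        amp, _ = saccade_metrics([iv])
        assert amp[0] == 0.0

    def test_no_saccades_is_error(self):
        with pytest.raises(ValueError):
            saccade_metrics([EyeMovementInterval("fixation", 0.0, 1.0, 0.0, 0.0)])

    def test_fixation_metrics_include_pursuit(self):
        intervals = [
            EyeMovementInterval("fixation", 0.0, 0.22, 0.0, 0.0),
            EyeMovementInterval("smooth_pursuit", 0.22, 0.52, 5.0, 1.5),
            EyeMovementInterval("saccade", 0.52, 0.55, 200.0, 4.0),
        ]
        durations, count = fixation_metrics(intervals)
        assert count == 2
        np.testing.assert_allclose(durations, [0.22, 0.3])

    def test_single_fixation_duration(self):
        durations, _ = fixation_metrics([EyeMovementInterval("fixation", 0.0, 0.22, 0.0, 0.0)])
        assert durations[0] == pytest.approx(0.22)

    def test_empty_intervals(self):
        durations, count = fixation_metrics([])
        assert count == 0 and durations.size == 0
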