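import numpy as np
import pytest
from scipy import ndimage

from retstim.optic_flow import (
    HorizontalFlowTrace,
    OknSegment,
    average_horizontal_flow,
    detect_flow_peaks,
    extract_okn_segments,
    okn_amplitude_frequency,
    poly_expansion,
    polynomial_expansion_flow,
)


@pytest.fixture(scope="module")
def smooth_texture():
    rng = np.random.default_rng(0)
    img = ndimage.gaussian_filter(rng.standard_normal((135, 240)), 3)
    return (img - img.min()) / np.ptp(img) * 255


class TestPolyExpansion:
    def test_exact_quadratic_recovery(self):
        yy, xx = np.mgrid[0:31, 0:31].astype(float)
        x, y = xx - 15, yy - 15
        A_true = np.array([[0.3, 0.1], [0.1, -0.2]])
        b_true = np.array([1.5, -0.7])
        c_true = 4.0
        quad = (
            A_true[0, 0] * x**2
            + A_true[1, 1] * y**2
            + 2 * A_true[0, 1] * x * y
            + b_true[0] * x
            + b_true[1] * y
            + c_true
        )
        A, b, c = poly_expansion(quad)
        assert np.abs(A[15, 15] - A_true).max() < 1e-9
        assert np.abs(b[15, 15] - b_true).max() < 1e-9
        assert abs(c[15, 15] - c_true) < 1e-9

    def test_A_symmetric(self, smooth_texture):
        A, _, _ = poly_expansion(smooth_texture)
        np.testing.assert_allclose(A[..., 0, 1], A[..., 1, 0])


class TestFlow:
    def test_identical_frames_zero_field(self, smooth_texture):
        flow = polynomial_expansion_flow(smooth_texture, smooth_texture)
        assert np.abs(flow.magnitude).max() < 0.05

    def test_three_px_translation(self, smooth_texture):
        shifted = ndimage.shift(smooth_texture, (0, 3.0), order=3, mode="nearest")
        flow = polynomial_expansion_flow(smooth_texture, shifted)
        core = flow.dx[10:-10, 10:-10]
        assert core.mean() == pytest.approx(3.0, abs=0.25)
        assert abs(flow.dy[10:-10, 10:-10].mean()) < 0.1

    def test_subpixel_translation(self, smooth_texture):
        shifted = ndimage.shift(smooth_texture, (0, 0.5), order=3, mode="nearest")
        flow = polynomial_expansion_flow(smooth_texture, shifted)
        mae = np.abs(flow.dx[10:-10, 10:-10] - 0.5).mean()
        assert mae < 0.2

    def test_antisymmetry(self, smooth_texture):
        shifted = ndimage.shift(smooth_texture, (0, 2.0), order=3, mode="nearest")
        fwd = polynomial_expansion_flow(smooth_texture, shifted)
        bwd = polynomial_expansion_flow(shifted, smooth_texture)
        asym = np.abs(fwd.dx[10:-10, 10:-10] + bwd.dx[10:-10, 10:-10]).mean()
        assert asym < 0.1

    def test_too_small_frames(self):
        with pytest.raises(ValueError, match="too small"):
            polynomial_expansion_flow(np.zeros((20, 20)), np.zeros((20, 20)), n_scales=5)

    def test_mismatched_shapes(self):
        with pytest.raises(ValueError):
            polynomial_expansion_flow(np.zeros((30, 30)), np.zeros((40, 40)), n_scales=1)


class TestHorizontalFlowTrace:
    def _pan_frames(self, velocities_px, rng_seed=1):
        rng = np.random.default_rng(rng_seed)
        pano = ndimage.gaussian_filter(rng.standard_normal((80, 500)), 2) * 60 + 128
        frames = []
        offset = 100.0
        for v in velocities_px:
            offset += v
            frames.append(
                ndimage.shift(pano, (0, -offset), order=1, mode="nearest")[:, 100:300]
            )
        return np.stack(frames)

    def test_static_scene(self):
        frames = self._pan_frames([0.0] * 5)
        trace = average_horizontal_flow(frames, n_scales=3, n_iterations=3)
        assert np.abs(trace.mean_dx_px).max() < 0.05

    def test_rightward_pan(self):
        # panorama slides left under the window -> scene content moves left;
        # pan the window rightward so content shifts RIGHT in the image
        frames = self._pan_frames([-3.0] * 5)
        trace = average_horizontal_flow(frames, n_scales=3, n_iterations=5)
        np.testing.assert_allclose(trace.mean_dx_px, 3.0, atol=0.3)

    def test_leftward_pan_negative(self):
        frames = self._pan_frames([3.0] * 5)
        trace = average_horizontal_flow(frames, n_scales=3, n_iterations=5)
        assert (trace.mean_dx_px < -2.0).all()

    def test_single_frame_rejected(self):
        with pytest.raises(ValueError):
            average_horizontal_flow(np.zeros((1, 50, 50)))


class TestPeakDetection:
    def _trace(self, values, rate=25.0):
        t = (np.arange(len(values)) + 1) / rate
        return HorizontalFlowTrace(t=t, mean_dx_px=np.asarray(values, float))

    def test_single_bump(self):
        v = np.zeros(1000)
        v[300:320] = np.hanning(20) * 5.0
        trace = self._trace(v)
        peaks = detect_flow_peaks(trace)
        assert peaks.size == 1
        assert abs(peaks[0] - 310 / 25.0) < 0.3

    def test_bump_in_final_10s_excluded(self):
        v = np.zeros(500)  # 20 s at 25 Hz
        v[400:420] = np.hanning(20) * 5.0  # at ~16.4 s, inside the final 10 s
        assert detect_flow_peaks(self._trace(v)).size == 0

    def test_all_below_threshold(self):
        v = np.zeros(1000)
        v[300:320] = np.hanning(20) * 5.0
        trace = self._trace(v)
        assert detect_flow_peaks(trace, reference_max=100.0).size == 0

    def test_negative_peaks_counted(self):
        v = np.zeros(1000)
        v[300:320] = -np.hanning(20) * 5.0
        assert detect_flow_peaks(self._trace(v)).size == 1


class TestOknSegments:
    def _eye(self, duration_s=30.0, rate=50.0, f=3.0, amp=1.0):
        t = np.arange(int(duration_s * rate)) / rate
        return t, amp * np.sin(2 * np.pi * f * t)

    def test_full_window(self):
        t, eye = self._eye()
        segs = extract_okn_segments(t, eye, np.array([15.0]))
        assert len(segs) == 1
        assert segs[0].samples.size == 100

    def test_low_valid_count_rejected(self):
        t, eye = self._eye()
        eye = eye.copy()
        eye[int(14.0 * 50) : int(15.0 * 50)] = np.nan  # 50 invalid of 100
        assert extract_okn_segments(t, eye, np.array([15.0])) == []

    def test_peak_near_start_rejected(self):
        t, eye = self._eye()
        assert extract_okn_segments(t, eye, np.array([0.5])) == []

    def test_interpolation_of_few_invalids(self):
        t, eye = self._eye()
        eye = eye.copy()
        eye[int(15.0 * 50) : int(15.0 * 50) + 10] = np.nan
        segs = extract_okn_segments(t, eye, np.array([15.0]))
        assert len(segs) == 1
        assert np.isfinite(segs[0].samples).all()
        assert segs[0].valid_count == 90


class TestOknSpectrum:
    def _segment(self, f, amps):
        t = np.arange(100) / 50.0
        sig = sum(a * np.sin(2 * np.pi * fi * t) for fi, a in zip(np.atleast_1d(f), amps))
        return OknSegment(samples=np.asarray(sig), valid_count=100, peak_time_s=0.0)

    def test_pure_3hz(self):
        seg = self._segment([3.0], [1.0])
        _, freq = okn_amplitude_frequency(seg)
        assert freq == pytest.approx(3.0, abs=0.01)
        assert not seg.low_confidence

    def test_mixture_larger_wins(self):
        seg = self._segment([2.5, 5.0], [0.5, 1.5])
        _, freq = okn_amplitude_frequency(seg)
        assert freq == pytest.approx(5.0, abs=0.01)

    def test_out_of_band_flags_low_confidence(self):
        seg = self._segment([1.0], [1.0])
        okn_amplitude_frequency(seg)
        assert seg.low_confidence


class TestEndToEnd:
    def test_turn_count_and_okn_frequency(self, walking_session, walking_flow):
        from retstim.session_io import gaze_to_degrees

        session, truth = walking_session
        _, peaks = walking_flow
        assert abs(peaks.size - len(truth.turn_times)) <= 1
        for t0 in truth.turn_times:
            assert np.min(np.abs(peaks - t0)) < 1.0

        az, _, ok = gaze_to_degrees(session.gaze.gp3)
        eye = np.where(session.gaze.validity & ok, az, np.nan)
        segs = extract_okn_segments(
            session.gaze.t, eye, peaks, blink_mask=truth.blink_mask(session.gaze.t)
        )
        assert segs
        for seg in segs:
            assert abs(seg.dominant_frequency_hz - truth.okn_frequency_hz) <= 0.5
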