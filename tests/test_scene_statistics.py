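import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from retstim.scene_statistics import (
    alpha_function,
    average_power_spectrum,
    fit_alpha,
    fit_gaussian,
    gaussian,
    half_range_eccentricity,
    luminance_skewness,
    mean_pixel_intensity,
    retinal_illuminance_trolands,
    rms_contrast,
)
from retstim.session_io import CameraModel


# --- independent two-pass loop oracles -------------------------------------


def loop_contrast(L, axis):
    """Naive per-row/column oracle for the N-1-divisor RMS contrast."""
    out = []
    vectors = L.T if axis == "space" else L
    for v in vectors:
        v = v[np.isfinite(v)]
        if v.size < 2:
            out.append(np.nan)
            continue
        mu = sum(v) / len(v)
        out.append(np.sqrt(sum((x - mu) ** 2 for x in v) / (len(v) - 1)))
    return np.array(out)


def loop_skewness(L, axis):
    """Naive oracle for the N-divisor normalized third moment."""
    out = []
    contrasts = loop_contrast(L, axis)
    vectors = L.T if axis == "space" else L
    for v, c in zip(vectors, contrasts):
        v = v[np.isfinite(v)]
        if v.size < 2 or not np.isfinite(c) or c == 0:
            out.append(np.nan)
            continue
        mu = sum(v) / len(v)
        out.append(sum(((x - mu) / c) ** 3 for x in v) / len(v))
    return np.array(out)


class TestRmsContrast:
    def test_four_pixel_worked_example(self):
        L = np.array([[0.0], [0.0], [0.0], [1.0]])
        assert rms_contrast(L, "space")[0] == pytest.approx(0.5, abs=1e-15)

    def test_constant_is_zero(self):
        L = np.full((10, 3), 0.7)
        assert np.allclose(rms_contrast(L, "space"), 0.0)
        assert np.allclose(rms_contrast(L, "time"), 0.0)

    def test_closed_form_binary(self):
        # k ones among N: C = sqrt(k (N-k) / (N (N-1)))
        n, k = 1000, 500
        L = np.concatenate([np.ones(k), np.zeros(n - k)])[:, None]
        expected = np.sqrt(k * (n - k) / (n * (n - 1)))
        assert rms_contrast(L, "space")[0] == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(0.50025, abs=5e-6)

    def test_matches_loop_oracle_random(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            L = rng.random((50, 50))
            np.testing.assert_allclose(rms_contrast(L, "space"), loop_contrast(L, "space"), atol=1e-12)
            np.testing.assert_allclose(rms_contrast(L, "time"), loop_contrast(L, "time"), atol=1e-12)

    def test_single_valid_entry_flagged(self):
        L = np.array([[0.5], [np.nan], [np.nan]])
        assert np.isnan(rms_contrast(L, "space")[0])


class TestLuminanceSkewness:
    def test_four_pixel_positive(self):
        L = np.array([[0.0], [0.0], [0.0], [1.0]])
        assert luminance_skewness(L, "space")[0] == pytest.approx(0.75, abs=1e-12)

    def test_four_pixel_negative_mirror(self):
        L = np.array([[1.0], [1.0], [1.0], [0.0]])
        assert luminance_skewness(L, "space")[0] == pytest.approx(-0.75, abs=1e-12)

    def test_symmetric_is_zero(self):
        L = np.array([[0.0], [1.0], [0.0], [1.0]])
        assert luminance_skewness(L, "space")[0] == pytest.approx(0.0, abs=1e-12)

    def test_zero_contrast_flagged(self):
        L = np.full((5, 2), 0.3)
        assert np.isnan(luminance_skewness(L, "space")).all()

    def test_matches_loop_oracle_random(self):
        rng = np.random.default_rng(1)
        for _ in range(5):
            L = rng.random((50, 50))
            np.testing.assert_allclose(
                luminance_skewness(L, "space"), loop_skewness(L, "space"), atol=1e-12
            )
            np.testing.assert_allclose(
                luminance_skewness(L, "time"), loop_skewness(L, "time"), atol=1e-12
            )


@settings(max_examples=30, deadline=None)
@given(
    seed=st.integers(0, 10_000),
    shift=st.floats(-0.2, 0.2),
    scale=st.floats(0.1, 2.0),
)
def test_affine_invariance_properties(seed, shift, scale):
    rng = np.random.default_rng(seed)
    L = rng.random((20, 8))
    c0 = rms_contrast(L, "space")
    sk0 = luminance_skewness(L, "space")
    # shift leaves contrast and skewness unchanged
    np.testing.assert_allclose(rms_contrast(L + shift, "space"), c0, atol=1e-10)
    np.testing.assert_allclose(luminance_skewness(L + shift, "space"), sk0, atol=1e-8)
    # scaling scales contrast by k, leaves skewness unchanged
    np.testing.assert_allclose(rms_contrast(L * scale, "space"), c0 * scale, atol=1e-10)
    np.testing.assert_allclose(luminance_skewness(L * scale, "space"), sk0, atol=1e-8)


@settings(max_examples=30, deadline=None)
@given(seed=st.integers(0, 10_000))
def test_skewness_odd_under_polarity_inversion(seed):
    rng = np.random.default_rng(seed)
    L = rng.random((30, 4))
    mu = L.mean(axis=0, keepdims=True)
    mirrored = -(L - mu) + mu
    np.testing.assert_allclose(
        luminance_skewness(mirrored, "space"),
        -luminance_skewness(L, "space"),
        atol=1e-8,
    )


class TestMeanIntensity:
    def test_all_ones(self):
        mu, grand = mean_pixel_intensity(np.ones((5, 3)))
        assert np.allclose(mu, 1.0) and grand == 1.0

    def test_half_and_half(self):
        L = np.concatenate([np.ones((5, 2)), np.zeros((5, 2))], axis=0)
        _, grand = mean_pixel_intensity(L)
        assert grand == 0.5

    def test_arithmetic(self):
        mu, grand = mean_pixel_intensity(np.array([[0.2], [0.4], [0.6]]))
        assert grand == pytest.approx(0.4, abs=1e-15)


class TestSpectrum:
    CAM = CameraModel(scene_resolution_px=(192, 108))

    def test_constant_frames_dc_only(self):
        frames = np.full((3, 108, 192), 100.0)
        res = average_power_spectrum(frames, self.CAM)
        nonzero = res.power[res.frequencies_cpd > 0.1]
        assert res.power[0] > 1e6
        # only window-sidelobe leakage beyond DC
        assert (nonzero < 1e-6 * res.power[0]).all()

    def test_grating_peak_at_f0(self):
        ppd_h = 192 / 82.0
        f0 = 0.5  # cycles/deg
        x = np.arange(192) / ppd_h
        frame = 128 + 100 * np.sin(2 * np.pi * f0 * x)
        frames = np.tile(frame, (2, 108, 1))
        res = average_power_spectrum(frames, self.CAM)
        mask = res.frequencies_cpd > 0.1
        peak = res.frequencies_cpd[mask][np.argmax(res.power[mask])]
        assert peak == pytest.approx(f0, abs=0.05)

    def test_white_noise_flat(self):
        rng = np.random.default_rng(0)
        frames = rng.normal(size=(8, 108, 192))
        res = average_power_spectrum(frames, self.CAM)
        mask = res.frequencies_cpd > 0.15
        x = np.log10(res.frequencies_cpd[mask])
        y = np.log10(res.power[mask])
        slope = np.polyfit(x, y, 1)[0]
        assert abs(slope) < 0.1

    def test_frequencies_below_nyquist(self):
        res = average_power_spectrum(np.zeros((1, 108, 192)), self.CAM)
        assert (np.diff(res.frequencies_cpd) > 0).all()
        assert res.frequencies_cpd[-1] <= min(self.CAM.ppd) / 2 + 0.05


class TestHalfRange:
    def test_linear_ramp_midpoint(self):
        d = np.array([5, 10, 15, 20, 25, 30, 60], float)
        y = (d - 5) / 55.0
        assert half_range_eccentricity(d, y) == pytest.approx(32.5)

    def test_step_interpolation(self):
        d = np.array([5, 10, 15, 20, 25, 30, 60], float)
        y = (d >= 20).astype(float)
        assert half_range_eccentricity(d, y) == pytest.approx(17.5)

    def test_constant_flagged(self):
        assert np.isnan(half_range_eccentricity([5, 10, 15], [1.0, 1.0, 1.0]))


class TestTrolands:
    def test_black_background(self):
        t = retinal_illuminance_trolands(2.0, 4.24)
        assert t == pytest.approx(28.22, rel=0.01)

    def test_white_background(self):
        t = retinal_illuminance_trolands(90.0, 3.70)
        assert t == pytest.approx(965.94, rel=0.01)

    def test_bright_sky(self):
        t = retinal_illuminance_trolands(9500.0, 2.09)
        assert t == pytest.approx(32484.11, rel=0.01)

    def test_unit_area_pupil(self):
        d = 2.0 / np.sqrt(np.pi)  # area exactly 1 mm^2
        assert retinal_illuminance_trolands(37.0, d) == pytest.approx(37.0, abs=1e-9)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            retinal_illuminance_trolands(0.0, 3.0)
        with pytest.raises(ValueError):
            retinal_illuminance_trolands(10.0, -1.0)


class TestGaussianFit:
    def test_noiseless_recovery(self):
        x = np.linspace(-4, 4, 60)
        y = gaussian(x, 0.0, 1.0, 0.0, 1.0)
        fit = fit_gaussian(x, y)
        assert fit.success
        assert fit.b == pytest.approx(0.0, abs=1e-6)
        assert fit.a == pytest.approx(1.0, abs=1e-6)
        assert fit.mu == pytest.approx(0.0, abs=1e-6)
        assert fit.sigma == pytest.approx(1.0, abs=1e-6)

    def test_peak_identity(self):
        fit = fit_gaussian(np.linspace(-3, 3, 40), gaussian(np.linspace(-3, 3, 40), 0.5, 2.0, 1.0, 0.7))
        assert fit.predict(fit.mu) == pytest.approx(fit.b + fit.a, abs=1e-6)

    def test_noisy_recovery_within_5pct(self):
        rng = np.random.default_rng(42)
        x = np.linspace(-5, 5, 100)
        truth = (0.1, 2.0, 0.5, 1.2)
        y = gaussian(x, *truth) + rng.normal(0, 0.01, x.size)
        fit = fit_gaussian(x, y)
        for got, want in zip((fit.a, fit.mu, fit.sigma), truth[1:]):
            assert got == pytest.approx(want, abs=0.05 * max(abs(want), 1.0))

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            fit_gaussian([0, 1, 2], [0, 1, 0])


class TestAlphaFit:
    def test_value_at_origin(self):
        # y(a) = max(0, b) because the rise term vanishes at x = a
        for b in (0.0, 0.4, -0.2):
            y = alpha_function(np.array([0.1]), b, 1.0, 0.5, 0.1)
            assert y[0] == pytest.approx(max(0.0, b), abs=1e-12)

    def test_peak_at_a_plus_r(self):
        # dy/dx = 0 at x = a + r, where y = b + d (calculus oracle)
        b, d, r, a = 0.2, 1.5, 0.5, 0.1
        xs = np.linspace(a, a + 3, 2001)
        ys = alpha_function(xs, b, d, r, a)
        assert xs[np.argmax(ys)] == pytest.approx(a + r, abs=2e-3)
        assert ys.max() == pytest.approx(b + d, abs=1e-6)

    def test_noiseless_self_consistency(self):
        x = np.linspace(0, 3, 80)
        truth = (0.0, 1.0, 0.5, 0.1)
        y = alpha_function(x, *truth)
        fit = fit_alpha(x, y)
        assert fit.success
        for got, want in zip((fit.b, fit.d, fit.r, fit.a), truth):
            assert got == pytest.approx(want, abs=1e-4)

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            fit_alpha([0, 1, 2, 3], [0, 1, 0, 0])
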