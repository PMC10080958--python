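"""Spatiotemporal luminance statistics of gaze-centered scene samples.

The two central quantities are RMS contrast and luminance skewness of
L(s, t), computed either across space (per retained frame) or across
time (per retinal offset).  Note the deliberately different divisors:
contrast uses N - 1 inside the root, skewness uses N — both follow the
printed definitions and must not be "fixed".

Also provided: mean pixel intensity, radially averaged spatial-frequency
spectra, the half-range eccentricity of aperture profiles, retinal
illuminance in trolands, and Gaussian / Alpha distribution fits.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .retinal_sampling import LOW_CONFIDENCE_N, LuminanceMatrix
from .session_io import CameraModel

__all__ = [
    "SpatioTemporalStats",
    "GaussianFitParams",
    "AlphaFitParams",
    "SpectrumResult",
    "rms_contrast",
    "luminance_skewness",
    "mean_pixel_intensity",
    "spatiotemporal_stats",
    "average_power_spectrum",
    "half_range_eccentricity",
    "retinal_illuminance_trolands",
    "fit_gaussian",
    "fit_alpha",
    "gaussian",
    "alpha_function",
]


def _as_matrix(L) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(L, LuminanceMatrix):
        return L.L, L.valid
    arr = np.asarray(L, dtype=float)
    return arr, np.isfinite(arr)


def _reduce_axis(axis: str) -> int:
    # "space" reduces over offsets (rows, axis 0) -> one value per frame;
    # "time" reduces over frames (columns, axis 1) -> one value per offset.
    if axis == "space":
        return 0
    if axis == "time":
        return 1
    raise ValueError(f"axis must be 'space' or 'time', got {axis!r}")


def valid_counts(L, axis: str) -> np.ndarray:
    arr, valid = _as_matrix(L)
    return valid.sum(axis=_reduce_axis(axis))


def rms_contrast(L, axis: str) -> np.ndarray:
    """RMS contrast along ``axis`` ('space' -> C_S(t), 'time' -> C_T(s)).

    C = sqrt( sum (L - mu)^2 / (N - 1) ) over valid cells only; rows or
    columns with fewer than 2 valid cells come back NaN (undefined).
    """
    arr, valid = _as_matrix(L)
    ax = _reduce_axis(axis)
    n = valid.sum(axis=ax)
    masked = np.where(valid, arr, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mu = masked.sum(axis=ax) / n
        dev = np.where(valid, arr - np.expand_dims(mu, ax), 0.0)
        c = np.sqrt((dev**2).sum(axis=ax) / (n - 1))
    c = np.asarray(c, dtype=float)
    c[n < 2] = np.nan
    # numerically-constant rows/columns: snap rounding residue to exact 0
    c[c < 1e-10] = 0.0
    return c


def luminance_skewness(L, axis: str) -> np.ndarray:
    """Luminance skewness along ``axis`` ('space' -> SK_S(t), 'time' -> SK_T(s)).

    SK = mean over valid cells of ((L - mu) / C)^3, with C the RMS
    contrast of the same row/column.  C == 0 (or undefined) -> NaN.
    Negative values mean dark-dominated, positive light-dominated.
    """
    arr, valid = _as_matrix(L)
    ax = _reduce_axis(axis)
    n = valid.sum(axis=ax)
    masked = np.where(valid, arr, 0.0)
    c = rms_contrast(L, axis)
    with np.errstate(invalid="ignore", divide="ignore"):
        mu = masked.sum(axis=ax) / n
        z = np.where(valid, (arr - np.expand_dims(mu, ax)) / np.expand_dims(c, ax), 0.0)
        sk = (z**3).sum(axis=ax) / n
    sk = np.asarray(sk, dtype=float)
    sk[(n < 2) | ~np.isfinite(c) | (c == 0)] = np.nan
    return sk


def mean_pixel_intensity(L, axis: str = "space") -> tuple[np.ndarray, float]:
    """Per-row/column mean of valid cells plus the grand mean, in [0, 1]."""
    arr, valid = _as_matrix(L)
    ax = _reduce_axis(axis)
    n = valid.sum(axis=ax)
    masked = np.where(valid, arr, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mu = masked.sum(axis=ax) / n
    mu = np.asarray(mu, dtype=float)
    mu[n < 1] = np.nan
    grand = float(masked.sum() / valid.sum()) if valid.any() else float("nan")
    return mu, grand


def _summary(values: np.ndarray) -> dict:
    finite = values[np.isfinite(values)]
    if finite.size == 0:
        return {"mean": float("nan"), "sd": float("nan"), "n": 0}
    sd = float(np.std(finite, ddof=1)) if finite.size > 1 else 0.0
    return {"mean": float(np.mean(finite)), "sd": sd, "n": int(finite.size)}


@dataclass
class SpatioTemporalStats:
    """All six per-frame / per-offset statistics plus mean ± sd summaries."""

    C_S: np.ndarray
    C_T: np.ndarray
    SK_S: np.ndarray
    SK_T: np.ndarray
    mu_S: np.ndarray
    mu_T: np.ndarray
    low_confidence_space: np.ndarray = field(default=None)  # type: ignore[assignment]
    low_confidence_time: np.ndarray = field(default=None)  # type: ignore[assignment]
    summary: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.summary:
            self.summary = {
                name: _summary(getattr(self, name))
                for name in ("C_S", "C_T", "SK_S", "SK_T", "mu_S", "mu_T")
            }


def spatiotemporal_stats(L: LuminanceMatrix) -> SpatioTemporalStats:
    n_space = valid_counts(L, "space")
    n_time = valid_counts(L, "time")
    return SpatioTemporalStats(
        C_S=rms_contrast(L, "space"),
        C_T=rms_contrast(L, "time"),
        SK_S=luminance_skewness(L, "space"),
        SK_T=luminance_skewness(L, "time"),
        mu_S=mean_pixel_intensity(L, "space")[0],
        mu_T=mean_pixel_intensity(L, "time")[0],
        low_confidence_space=n_space < LOW_CONFIDENCE_N,
        low_confidence_time=n_time < LOW_CONFIDENCE_N,
    )


# ---------------------------------------------------------------------------
# Spatial-frequency spectrum


@dataclass
class SpectrumResult:
    frequencies_cpd: np.ndarray
    log10_power: np.ndarray
    n_frames: int
    power: np.ndarray = None  # type: ignore[assignment]


def average_power_spectrum(
    frames: np.ndarray,
    camera: CameraModel,
    bin_width_cpd: float = 0.05,
) -> SpectrumResult:
    """Radially averaged 2-D power spectrum, averaged over frames.

    Each frame is Hann-windowed (to curb edge leakage), Fourier
    transformed, and its power binned by radial spatial frequency in
    cycles/deg using the per-axis pixels-per-degree.
    """
    frames = np.asarray(frames, dtype=float)
    if frames.ndim == 2:
        frames = frames[None]
    n_frames, h, w = frames.shape[:3]
    ppd_h, ppd_v = camera.ppd
    # stored frames may be a rescaled version of the nominal resolution
    ppd_h *= w / camera.scene_resolution_px[0]
    ppd_v *= h / camera.scene_resolution_px[1]

    win = np.outer(np.hanning(h), np.hanning(w))
    fx = np.fft.fftfreq(w, d=1.0 / ppd_h)
    fy = np.fft.fftfreq(h, d=1.0 / ppd_v)
    fr = np.hypot(fy[:, None], fx[None, :])
    nyquist = min(ppd_h, ppd_v) / 2.0
    edges = np.arange(0.0, nyquist + bin_width_cpd, bin_width_cpd)
    which = np.digitize(fr.ravel(), edges) - 1
    n_bins = edges.size - 1
    in_range = (which >= 0) & (which < n_bins)
    counts = np.bincount(which[in_range], minlength=n_bins)

    acc = np.zeros(n_bins)
    for frame in frames:
        spec = np.abs(np.fft.fft2(frame * win)) ** 2
        acc += np.bincount(which[in_range], weights=spec.ravel()[in_range], minlength=n_bins)
    with np.errstate(invalid="ignore", divide="ignore"):
        power = acc / (counts * n_frames)
        logp = np.log10(power)
    centers = 0.5 * (edges[:-1] + edges[1:])
    keep = counts > 0
    return SpectrumResult(
        frequencies_cpd=centers[keep],
        log10_power=logp[keep],
        n_frames=n_frames,
        power=power[keep],
    )


def half_range_eccentricity(diameters, metric_values) -> float:
    """Diameter (deg) at which a metric first crosses half of its
    max-min range, by linear interpolation; NaN if it never crosses."""
    x = np.asarray(diameters, dtype=float)
    y = np.asarray(metric_values, dtype=float)
    if x.size < 3 or not np.all(np.isfinite(y)):
        raise ValueError("need >= 3 finite metric values")
    lo, hi = float(np.min(y)), float(np.max(y))
    if hi == lo:
        return float("nan")
    target = lo + 0.5 * (hi - lo)
    d = y - target
    for i in range(d.size - 1):
        if d[i] == 0:
            return float(x[i])
        if d[i] * d[i + 1] < 0 or d[i + 1] == 0:
            frac = d[i] / (d[i] - d[i + 1])
            return float(x[i] + frac * (x[i + 1] - x[i]))
    return float("nan")


def retinal_illuminance_trolands(luminance_cd_m2: float, pupil_diameter_mm: float) -> float:
    """T = L * pi * (d/2)^2, with L in cd/m^2 and d in mm."""
    if luminance_cd_m2 <= 0 or pupil_diameter_mm <= 0:
        raise ValueError("luminance and pupil diameter must be positive")
    return luminance_cd_m2 * np.pi * (pupil_diameter_mm / 2.0) ** 2


# ---------------------------------------------------------------------------
# Distribution fits


@dataclass
class GaussianFitParams:
    b: float
    a: float
    mu: float
    sigma: float
    goodness: float
    success: bool = True
    message: str = ""

    def predict(self, x):
        return gaussian(np.asarray(x, dtype=float), self.b, self.a, self.mu, self.sigma)


@dataclass
class AlphaFitParams:
    b: float
    d: float
    r: float
    a: float
    goodness: float
    success: bool = True
    message: str = ""

    def predict(self, x):
        return alpha_function(np.asarray(x, dtype=float), self.b, self.d, self.r, self.a)


def gaussian(x, b, a, mu, sigma):
    return b + a * np.exp(-((x - mu) ** 2) / (2.0 * sigma**2))


def alpha_function(x, b, d, r, a):
    z = (x - a) / r
    return np.maximum(0.0, b + d * z * np.exp(1.0 - z))


def _r_squared(y, y_hat) -> float:
    ss_res = float(np.sum((y - y_hat) ** 2))
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    return 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")


def fit_gaussian(x, y, maxfev: int = 20000) -> GaussianFitParams:
    """Least-squares Gaussian fit y = b + a exp(-(x-mu)^2 / 2 sigma^2).

    Initialized from histogram moments; sigma constrained positive.
    Non-convergence returns a flagged failure instead of raising.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 4:
        raise ValueError("need >= 4 points")
    b0 = float(np.min(y))
    a0 = float(np.max(y) - b0) or 1.0
    w = np.clip(y - b0, 0.0, None)
    if w.sum() > 0:
        mu0 = float(np.sum(x * w) / w.sum())
        var0 = float(np.sum((x - mu0) ** 2 * w) / w.sum())
        sigma0 = float(np.sqrt(var0)) or float(np.ptp(x)) / 4
    else:
        mu0, sigma0 = float(np.mean(x)), float(np.ptp(x)) / 4 or 1.0
    span = float(np.ptp(x)) or 1.0
    bounds = (
        [-np.inf, -np.inf, np.min(x) - span, 1e-12],
        [np.inf, np.inf, np.max(x) + span, 100 * span],
    )
    try:
        popt, _ = curve_fit(
            gaussian, x, y, p0=[b0, a0, mu0, max(sigma0, 1e-6)],
            bounds=bounds, maxfev=maxfev,
        )
    except RuntimeError as exc:
        return GaussianFitParams(b0, a0, mu0, sigma0, float("nan"),
                                 success=False, message=str(exc))
    fit = GaussianFitParams(*popt, goodness=float("nan"))
    fit.goodness = _r_squared(y, fit.predict(x))
    return fit


def fit_alpha(x, y, maxfev: int = 20000) -> AlphaFitParams:
    """Least-squares Alpha-function fit
    y = max(0, b + d ((x-a)/r) exp(1 - (x-a)/r)).

    The function peaks at x = a + r with value b + d.  Initialized from
    the rise point / peak location; r constrained positive.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 5:
        raise ValueError("need >= 5 points")
    order = np.argsort(x)
    xs, ys = x[order], y[order]
    b0 = float(np.min(ys))
    rng = float(np.ptp(ys)) or 1.0
    i_peak = int(np.argmax(ys))
    rise = np.nonzero(ys[: i_peak + 1] > b0 + 0.1 * rng)[0]
    a0 = float(xs[rise[0]]) if rise.size else float(xs[0])
    span = float(np.ptp(xs)) or 1.0
    r0 = max(float(xs[i_peak]) - a0, span / 20.0)
    d0 = rng
    bounds = (
        [-np.inf, -np.inf, 1e-9, np.min(xs) - span],
        [np.inf, np.inf, 100 * span, np.max(xs) + span],
    )
    try:
        popt, _ = curve_fit(
            alpha_function, x, y, p0=[b0, d0, r0, a0], bounds=bounds, maxfev=maxfev
        )
    except RuntimeError as exc:
        return AlphaFitParams(b0, d0, r0, a0, float("nan"),
                              success=False, message=str(exc))
    fit = AlphaFitParams(*popt, goodness=float("nan"))
    fit.goodness = _r_squared(y, fit.predict(x))
    return fit
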